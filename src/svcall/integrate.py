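"""Merge cluster- and coverage-derived evidence into unified SV calls.

Cluster calls (typed discordant-pair clusters with breakpoint confidence
intervals) and depth-of-coverage segments are combined: a DEL/DUP cluster
call and a sign-consistent DOC segment that reciprocally overlap by at
least ``min_reciprocal_overlap`` merge into one call carrying both evidence
classes; everything else passes through with its single evidence class.
Inversions, translocations and insertions are copy-neutral and never merge
with DOC segments.  Calls are written as VCF 4.2 (symbolic ALTs, paired BND
records for translocations) and the whole pipeline is exposed through
:func:`run_pipeline`.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pysam

from . import __version__ as _VERSION
from .alignments import (
    InsertSizeModel,
    LoadStats,
    ReadPairRecord,
    estimate_insert_model,
    load_read_pairs,
    split_by_discordancy,
)
from .clustering import (
    DiscordantCluster,
    breakpoint_intervals,
    cluster_discordant,
    filter_by_support,
    min_support_cutoff,
    write_bedpe,
)
from .doc import (
    CnvSegment,
    CoverageWindow,
    call_segments,
    choose_window_size,
    make_windows,
    write_bedgraph,
    write_segments_bed,
    write_windows_tsv,
)
from .filters import AnnotationTrack, apply_track_filters, rescue_discordant
from .sv_typing import SVType, assign_type

__all__ = [
    "SVCall",
    "cluster_to_call",
    "segment_to_call",
    "merge_calls",
    "reciprocal_overlap",
    "write_vcf",
    "read_vcf",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]


@dataclass
class SVCall:
    """A unified structural-variant call."""

    id: str
    svtype: SVType
    chrom1: str
    pos1: int
    ci1: tuple[int, int]
    chrom2: str
    pos2: int
    ci2: tuple[int, int]
    length: Optional[int] = None
    evidence: set = field(default_factory=set)
    support: int = 0
    log2_ratio: Optional[float] = None
    filters: list = field(default_factory=list)
    track_overlaps: dict = field(default_factory=dict)
    imprecise: bool = False
    strands: tuple[str, str] = ("+", "-")

    def __post_init__(self):
        if not self.evidence:
            raise ValueError("SV call requires at least one evidence class")
        if not (self.ci1[0] <= self.pos1 <= self.ci1[1]):
            raise ValueError(f"pos1 {self.pos1} outside CI {self.ci1}")
        if not (self.ci2[0] <= self.pos2 <= self.ci2[1]):
            raise ValueError(f"pos2 {self.pos2} outside CI {self.ci2}")

    @property
    def span(self) -> Optional[tuple[int, int]]:
        if self.chrom1 != self.chrom2:
            return None
        lo, hi = sorted((self.pos1, self.pos2))
        return (lo, max(hi, lo + 1))


def cluster_to_call(
    cluster: DiscordantCluster,
    model: InsertSizeModel,
    read_len: int,
    call_id: str,
) -> SVCall:
    """Turn a supported cluster into an SV call with CI-carrying breakpoints."""
    left, right = breakpoint_intervals(cluster, model, read_len)
    svtype = assign_type(cluster, model)
    length: Optional[int] = None
    if cluster.chrom1 == cluster.chrom2 and svtype in (SVType.DEL, SVType.DUP, SVType.INV):
        length = max(1, right.mid - left.mid)
    if svtype is SVType.INS and cluster.chrom1 == cluster.chrom2:
        # a small insertion is a point event: its two side-intervals overlap
        # around the single junction, so report one merged interval
        lo, hi = min(left.lo, right.lo), max(left.hi, right.hi)
        mid = (lo + hi) // 2
        return SVCall(
            id=call_id, svtype=svtype,
            chrom1=cluster.chrom1, pos1=mid, ci1=(lo, hi),
            chrom2=cluster.chrom2, pos2=mid + 1, ci2=(lo, hi),
            length=None, evidence={"cluster"}, support=cluster.support,
            strands=(cluster.strand1, cluster.strand2),
        )
    return SVCall(
        id=call_id,
        svtype=svtype,
        chrom1=cluster.chrom1,
        pos1=left.mid,
        ci1=(left.lo, left.hi),
        chrom2=cluster.chrom2,
        pos2=right.mid,
        ci2=(right.lo, right.hi),
        length=length,
        evidence={"cluster"},
        support=cluster.support,
        strands=(cluster.strand1, cluster.strand2),
    )


def segment_to_call(seg: CnvSegment, call_id: str) -> SVCall:
    """Turn a DOC segment into an imprecise DEL/DUP call (support 0)."""
    win = max(1, seg.window_span)
    svtype = SVType.DEL if seg.direction == "loss" else SVType.DUP
    return SVCall(
        id=call_id,
        svtype=svtype,
        chrom1=seg.chrom,
        pos1=seg.start,
        ci1=(max(0, seg.start - win), seg.start + win),
        chrom2=seg.chrom,
        pos2=seg.end,
        ci2=(max(0, seg.end - win), seg.end + win),
        length=seg.end - seg.start,
        evidence={"doc"},
        support=0,
        log2_ratio=seg.mean_log2_ratio,
        imprecise=True,
    )


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len_a, overlap/len_b); 0 when disjoint or degenerate."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    la, lb = a[1] - a[0], b[1] - b[0]
    if ov <= 0 or la <= 0 or lb <= 0:
        return 0.0
    return min(ov / la, ov / lb)


_SIGN = {SVType.DEL: "loss", SVType.DUP: "gain"}


def merge_calls(
    cluster_calls: Sequence[SVCall],
    doc_segments: Sequence[CnvSegment],
    min_reciprocal_overlap: float = 0.5,
) -> list[SVCall]:
    """Combine cluster calls with DOC segments into one sorted call list.

    Candidate (cluster call, segment) pairs — same chromosome, copy-number
    sign consistent, reciprocal overlap at or above the threshold — are
    matched greedily by decreasing overlap; each call and each segment is
    used at most once.  A DEL/DUP cluster call overlapping only an
    opposite-sign segment gains a ``discordant_evidence`` tag.  Unmatched
    segments become imprecise DOC-only calls.  Every input is represented
    in exactly one output call.
    """
    seg_calls = [segment_to_call(s, f"doc{i}") for i, s in enumerate(doc_segments)]
    candidates = []
    conflicts: set[int] = set()
    for ci, call in enumerate(cluster_calls):
        if call.svtype not in _SIGN or call.span is None:
            continue
        for si, seg in enumerate(seg_calls):
            if seg.chrom1 != call.chrom1:
                continue
            ov = reciprocal_overlap(call.span, (seg.pos1, seg.pos2))
            if ov < min_reciprocal_overlap:
                continue
            if _SIGN[call.svtype] == ("loss" if seg.svtype == SVType.DEL else "gain"):
                candidates.append((ov, ci, si))
            else:
                conflicts.add(ci)
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_c: set[int] = set()
    used_s: set[int] = set()
    merged_lr: dict[int, float] = {}
    for ov, ci, si in candidates:
        if ci in used_c or si in used_s:
            continue
        used_c.add(ci)
        used_s.add(si)
        merged_lr[ci] = seg_calls[si].log2_ratio

    out: list[SVCall] = []
    for ci, call in enumerate(cluster_calls):
        if ci in used_c:
            call.evidence = set(call.evidence) | {"doc"}
            call.log2_ratio = merged_lr[ci]
        elif ci in conflicts and "discordant_evidence" not in call.filters:
            call.filters.append("discordant_evidence")
        out.append(call)
    out.extend(sc for si, sc in enumerate(seg_calls) if si not in used_s)
    out.sort(key=lambda c: (c.chrom1, c.pos1, c.id))
    for i, call in enumerate(out, start=1):
        call.id = f"sv{i}"
    return out


# ---------------------------------------------------------------------------
# VCF emission / ingestion
# ---------------------------------------------------------------------------

_VCF_INFO_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
    '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS">',
    '##INFO=<ID=CIEND,Number=2,Type=Integer,Description="Confidence interval around END">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting discordant pair count">',
    '##INFO=<ID=LOG2R,Number=1,Type=Float,Description="Mean log2 coverage ratio over spanned windows">',
    '##INFO=<ID=EVIDENCE,Number=.,Type=String,Description="Evidence classes: cluster, doc">',
    '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise structural variant">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
    '##INFO=<ID=EVENT,Number=1,Type=String,Description="ID of the originating event">',
]
_VCF_ALT_LINES = [
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=DUP,Description="Tandem duplication">',
    '##ALT=<ID=INV,Description="Inversion">',
    '##ALT=<ID=INS,Description="Insertion of novel sequence">',
    '##ALT=<ID=CPX,Description="Complex rearrangement, manual interpretation required">',
]


def _bnd_alt(ref_base: str, here_right: bool, mate_chrom: str, mate_pos_1b: int,
             mate_right: bool) -> str:
    """VCF breakend ALT.  ``here_right``: the junction lies to the right of
    this breakend; ``mate_right``: same for the mate side."""
    if mate_right:
        bracket = f"]{mate_chrom}:{mate_pos_1b}]"
    else:
        bracket = f"[{mate_chrom}:{mate_pos_1b}["
    return ref_base + bracket if here_right else bracket + ref_base


def _fmt_filters(call: SVCall) -> str:
    return ";".join(call.filters) if call.filters else "PASS"


def _fmt_info(parts: list[str]) -> str:
    return ";".join(parts)


def write_vcf(
    calls: Sequence[SVCall],
    contigs: Sequence[tuple[str, int]],
    path: str,
    sample_name: str = "SAMPLE",
    expected_orientation: str = "FR",
) -> None:
    """Write calls as VCF 4.2 with symbolic ALTs and paired BND records.

    POS is the base before the breakpoint (1-based anchor convention: a
    0-based half-open event [s, e) is written with POS = s, END = e);
    CIPOS/CIEND carry the breakpoint-interval uncertainty as offsets.
    Output is deterministic: rerunning on identical calls yields identical
    bytes.
    """
    order = {name: i for i, (name, _) in enumerate(contigs)}
    for c in calls:
        for chrom in (c.chrom1, c.chrom2):
            if chrom not in order:
                raise ValueError(f"call chromosome {chrom!r} absent from contigs")
    from ._util import strands_of

    pointing = strands_of(expected_orientation)[0]
    rows: list[tuple[int, int, str, str]] = []
    for call in calls:
        common = [f"SUPPORT={call.support}"]
        if call.log2_ratio is not None:
            common.append(f"LOG2R={call.log2_ratio:.4f}")
        common.append("EVIDENCE=" + ",".join(sorted(call.evidence)))
        if call.imprecise:
            common.append("IMPRECISE")
        filt = _fmt_filters(call)

        if call.svtype is SVType.TRA:
            right1 = call.strands[0] == pointing
            right2 = call.strands[1] == pointing
            p1, p2 = max(1, call.pos1), max(1, call.pos2)
            for k, (chrom, pos, ci, here_right, mchrom, mpos, mate_right) in enumerate(
                (
                    (call.chrom1, p1, call.ci1, right1, call.chrom2, p2, right2),
                    (call.chrom2, p2, call.ci2, right2, call.chrom1, p1, right1),
                ),
                start=1,
            ):
                rid = f"{call.id}_{k}"
                mid = f"{call.id}_{3 - k}"
                info = [
                    "SVTYPE=BND",
                    f"CIPOS={ci[0] - pos},{ci[1] - pos}",
                    f"MATEID={mid}",
                    f"EVENT={call.id}",
                ] + common
                alt = _bnd_alt("N", here_right, mchrom, mpos, mate_right)
                rows.append(
                    (order[chrom], pos, rid,
                     f"{chrom}\t{pos}\t{rid}\tN\t{alt}\t.\t{filt}\t{_fmt_info(info)}")
                )
            continue

        pos = max(1, call.pos1)
        end = max(pos + 1, call.pos2)
        alt_id = "CPX" if call.svtype is SVType.COMPLEX else call.svtype.value
        info = [f"SVTYPE={alt_id}", f"END={end}"]
        if call.length is not None:
            svlen = -call.length if call.svtype is SVType.DEL else call.length
            info.append(f"SVLEN={svlen}")
        info.append(f"CIPOS={call.ci1[0] - pos},{call.ci1[1] - pos}")
        info.append(f"CIEND={call.ci2[0] - end},{call.ci2[1] - end}")
        info += common
        rows.append(
            (order[call.chrom1], pos, call.id,
             f"{call.chrom1}\t{pos}\t{call.id}\tN\t<{alt_id}>\t.\t{filt}\t{_fmt_info(info)}")
        )

    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    filter_ids = sorted({f for c in calls for f in c.filters})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=svcall-{_VERSION}\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for line in _VCF_ALT_LINES:
            fh.write(line + "\n")
        for line in _VCF_INFO_LINES:
            fh.write(line + "\n")
        for fid in filter_ids:
            fh.write(f'##FILTER=<ID={fid},Description="Filter tag {fid}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, _, _, line in rows:
            fh.write(line + "\n")


def read_vcf(path: str) -> list[SVCall]:
    """Parse a VCF written by :func:`write_vcf` back into SV calls.

    BND mate pairs are re-joined into single TRA calls via MATEID/EVENT.
    """
    calls: list[SVCall] = []
    bnd_parts: dict[str, list] = {}
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            info = dict(rec.info)
            svtype = info.get("SVTYPE")
            evidence = set(info.get("EVIDENCE", ()))
            support = int(info.get("SUPPORT", 0))
            log2r = info.get("LOG2R")
            if log2r is not None:
                log2r = round(float(log2r), 4)
            filters = [f for f in rec.filter.keys() if f != "PASS"]
            imprecise = "IMPRECISE" in info
            pos = rec.pos  # 1-based == our 0-based breakpoint anchor
            if svtype == "BND":
                event = info["EVENT"]
                ci = info.get("CIPOS", (0, 0))
                bnd_parts.setdefault(event, []).append(
                    dict(
                        chrom=rec.chrom, pos=pos,
                        ci=(pos + int(ci[0]), pos + int(ci[1])),
                        alt=rec.alts[0], id=rec.id,
                        evidence=evidence, support=support,
                        filters=filters, imprecise=imprecise,
                    )
                )
                continue
            # pysam folds END into rec.stop (0-based exclusive == END value)
            end = int(info["END"]) if "END" in info else int(rec.stop)
            cipos = info.get("CIPOS", (0, 0))
            ciend = info.get("CIEND", (0, 0))
            alt_id = "COMPLEX" if svtype == "CPX" else svtype
            length = info.get("SVLEN")
            calls.append(
                SVCall(
                    id=rec.id,
                    svtype=SVType(alt_id),
                    chrom1=rec.chrom,
                    pos1=pos,
                    ci1=(pos + int(cipos[0]), pos + int(cipos[1])),
                    chrom2=rec.chrom,
                    pos2=end,
                    ci2=(end + int(ciend[0]), end + int(ciend[1])),
                    length=abs(int(length)) if length is not None else None,
                    evidence=evidence or {"cluster"},
                    support=support,
                    log2_ratio=log2r,
                    filters=filters,
                    imprecise=imprecise,
                )
            )
    for event, parts in sorted(bnd_parts.items()):
        parts.sort(key=lambda p: p["id"])
        a = parts[0]
        b = parts[1] if len(parts) > 1 else parts[0]
        strands = (
            "+" if a["alt"][0] not in "[]" else "-",
            "+" if b["alt"][0] not in "[]" else "-",
        )
        calls.append(
            SVCall(
                id=event,
                svtype=SVType.TRA,
                chrom1=a["chrom"], pos1=a["pos"], ci1=a["ci"],
                chrom2=b["chrom"], pos2=b["pos"], ci2=b["ci"],
                evidence=a["evidence"] or {"cluster"},
                support=a["support"],
                filters=a["filters"],
                imprecise=a["imprecise"],
                strands=strands,
            )
        )
    calls.sort(key=lambda c: (c.chrom1, c.pos1, c.id))
    return calls


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All effective parameters of one pipeline run.

    ``sample``/``ref_sample`` are SAM/BAM paths or in-memory
    ``ReadPairRecord`` lists (the latter require ``contigs``).
    """

    sample: Union[str, list]
    ref_sample: Optional[Union[str, list]] = None
    fasta: Optional[str] = None
    tracks: Sequence[AnnotationTrack] = ()
    contigs: Optional[Sequence[tuple[str, int]]] = None
    out_dir: Optional[str] = None
    sample_name: str = "SAMPLE"
    read_len: Optional[int] = None
    min_mapq: int = 20
    drop_duplicates: bool = True
    k_discordant: float = 3.0
    robust_sigma: bool = True
    max_sample: int = 1_000_000
    freeze_means: bool = False
    support_floor: int = 2
    min_support: Optional[int] = None
    rescue: bool = True
    rescue_min_identity: float = 0.9
    doc_target_reads: int = 100
    doc_step_frac: float = 0.5
    z_threshold: float = 3.0
    min_consecutive: int = 3
    min_reciprocal_overlap: float = 0.5
    filter_mode: str = "annotate"
    track_max_frac: float = 0.5


@dataclass
class PipelineResult:
    model: InsertSizeModel
    clusters: list
    cluster_calls: list
    windows: list
    segments: list
    calls: list
    min_support: int
    n_pairs: int
    n_discordant: int
    n_rescued_away: int
    log: list


def _load_any(src, cfg: PipelineConfig, stats: LoadStats) -> list[ReadPairRecord]:
    if isinstance(src, str):
        return load_read_pairs(
            src, min_mapq=cfg.min_mapq, drop_duplicates=cfg.drop_duplicates,
            stats=stats, keep_seqs=cfg.fasta is not None,
        )
    stats.n_pairs = len(src)
    return list(src)


def _doc_positions(pairs: Iterable[ReadPairRecord], read_len: int) -> dict[str, np.ndarray]:
    """5'-most mapped base of every read, grouped by chromosome."""
    acc: dict[str, list[int]] = {}
    shift = read_len - 1
    for p in pairs:
        acc.setdefault(p.chrom1, []).append(p.alpha + shift if p.strand1 == "-" else p.alpha)
        acc.setdefault(p.chrom2, []).append(p.beta + shift if p.strand2 == "-" else p.beta)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in acc.items()}


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute alignments -> clustering -> typing -> (DOC) -> filters -> merge.

    Deterministic given fixed inputs; writes VCF/BEDPE/bedGraph/TSV outputs
    and a run log with all effective parameters when ``out_dir`` is set.
    """
    log: list[str] = [f"svcall {_VERSION}"]
    stats = LoadStats()
    pairs = _load_any(cfg.sample, cfg, stats)
    if not pairs:
        raise ValueError("no usable read pairs in sample input")
    if cfg.contigs is not None:
        contigs = list(cfg.contigs)
    elif stats.contigs:
        contigs = list(stats.contigs.items())
    else:
        raise ValueError("contigs must be provided for in-memory record input")
    genome_size = sum(l for _, l in contigs)
    read_len = cfg.read_len or stats.read_length or 50
    log.append(f"sample pairs: {len(pairs)} (orphans {stats.n_orphans}, "
               f"dups skipped {stats.n_duplicates_skipped}, low mapq {stats.n_low_mapq})")

    model = estimate_insert_model(
        pairs, k_discordant=cfg.k_discordant, max_sample=cfg.max_sample,
        robust=cfg.robust_sigma,
    )
    log.append(
        f"insert model: median={model.median_is:.0f} sigma={model.sigma_is:.1f} "
        f"orientation={model.expected_orientation} k={model.k_discordant} "
        f"(n={model.n_pairs_sampled})"
    )

    sample_doc_pos = None
    if cfg.ref_sample is not None:
        sample_doc_pos = _doc_positions(pairs, read_len)

    concordant, discordant = split_by_discordancy(pairs, model)
    n_pairs = len(pairs)
    del pairs, concordant  # counts kept; free memory before reference load
    log.append(f"discordant pairs: {len(discordant)} / {n_pairs}")

    n_rescued = 0
    if cfg.rescue and cfg.fasta is not None and any(
        p.seq1 is not None and p.seq2 is not None for p in discordant
    ):
        import pyfaidx

        ref = pyfaidx.Fasta(cfg.fasta)
        discordant, n_rescued = rescue_discordant(
            discordant, ref, model, min_identity_frac=cfg.rescue_min_identity
        )
        log.append(f"realignment rescue discarded {n_rescued} artifact pairs")
    else:
        log.append("realignment rescue skipped (no reference FASTA or no sequences)")

    physical_coverage = n_pairs * model.median_is / genome_size
    min_support = (
        cfg.min_support
        if cfg.min_support is not None
        else min_support_cutoff(physical_coverage, floor=cfg.support_floor)
    )
    log.append(f"physical coverage {physical_coverage:.1f}x -> min support {min_support}")

    clusters = cluster_discordant(discordant, model, freeze_means=cfg.freeze_means)
    supported = filter_by_support(clusters, max(2, min_support))
    log.append(f"clusters: {len(clusters)} raw, {len(supported)} with support >= "
               f"{max(2, min_support)}")
    cluster_calls = [
        cluster_to_call(c, model, read_len, f"c{i}") for i, c in enumerate(supported)
    ]

    windows: list[CoverageWindow] = []
    segments: list[CnvSegment] = []
    if cfg.ref_sample is not None:
        ref_stats = LoadStats()
        ref_pairs = _load_any(cfg.ref_sample, cfg, ref_stats)
        ref_doc_pos = _doc_positions(ref_pairs, read_len)
        del ref_pairs
        total_s = sum(len(v) for v in sample_doc_pos.values())
        total_r = sum(len(v) for v in ref_doc_pos.values())
        window = choose_window_size(total_s, total_r, genome_size, cfg.doc_target_reads)
        step = max(1, int(window * cfg.doc_step_frac))
        windows = make_windows(sample_doc_pos, ref_doc_pos, dict(contigs), window, step)
        segments = call_segments(windows, cfg.z_threshold, cfg.min_consecutive)
        log.append(f"DOC: window {window} bp step {step}, {len(windows)} windows, "
                   f"{len(segments)} segments")
    else:
        log.append("DOC stage skipped: no reference sample provided")

    calls = merge_calls(cluster_calls, segments, cfg.min_reciprocal_overlap)
    if cfg.tracks:
        calls = apply_track_filters(
            calls, list(cfg.tracks), cfg.track_max_frac, cfg.filter_mode
        )
        log.append(f"track filters ({cfg.filter_mode}): {len(calls)} calls retained")
    log.append(f"final calls: {len(calls)}")

    result = PipelineResult(
        model=model,
        clusters=supported,
        cluster_calls=cluster_calls,
        windows=windows,
        segments=segments,
        calls=calls,
        min_support=min_support,
        n_pairs=n_pairs,
        n_discordant=len(discordant) + n_rescued,
        n_rescued_away=n_rescued,
        log=log,
    )
    if cfg.out_dir:
        _write_outputs(result, cfg, contigs, read_len)
    return result


def _write_outputs(res: PipelineResult, cfg: PipelineConfig, contigs, read_len) -> None:
    os.makedirs(cfg.out_dir, exist_ok=True)
    out = lambda name: os.path.join(cfg.out_dir, name)
    write_vcf(res.calls, contigs, out("calls.vcf"), cfg.sample_name,
              expected_orientation=res.model.expected_orientation)
    write_bedpe(res.clusters, res.model, read_len, out("clusters.bedpe"))
    if res.windows:
        write_windows_tsv(res.windows, out("doc_windows.tsv"))
        write_bedgraph(res.windows, out("doc_ratio.bedgraph"))
        write_segments_bed(res.segments, out("doc_segments.bed"))
    with open(out("run.log"), "w") as fh:
        fh.write("\n".join(res.log) + "\n")
        fh.write("# effective parameters\n")
        for k, v in sorted(vars(cfg).items()):
            if k in ("sample", "ref_sample") and not isinstance(v, (str, type(None))):
                v = f"<{len(v)} in-memory records>"
            if k == "tracks":
                v = [t.name for t in v] if v else []
            fh.write(f"{k} = {v}\n")
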