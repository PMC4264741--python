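"""Read-pair simulator with known truth for testing the SV caller.

A random reference genome is rearranged according to a list of SV
specifications (deletion, tandem duplication, inversion, insertion,
reciprocal translocation), producing a *donor* genome represented as a
list of blocks, each mapping back to a reference segment (possibly
reverse-complemented) or to novel inserted sequence.  Paired reads are then
drawn uniformly from the donor with a Normal insert-size distribution and
reported at their **reference** coordinates through the block map — no
aligner is involved, so pairs spanning an SV junction exhibit exactly the
canonical discordant signature for that SV type, while background pairs are
concordant.  Reads that would cross a junction within their own length are
dropped (a real aligner would soft-clip them; split-read evidence is not
modelled here).

Everything is reproducible from the seed, including the emitted SAM bytes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import numpy as np
import pysam

from .alignments import ReadPairRecord
from ._util import revcomp, strands_of

__all__ = [
    "SVSpec",
    "TruthSV",
    "TruthManifest",
    "Scenario",
    "make_reference",
    "apply_svs",
    "sample_pairs",
    "write_fasta",
    "write_sam",
    "write_truth",
    "default_scenario",
    "simulate_scenario",
    "expected_signature",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SVSpec:
    """One structural variant to implant.

    ``length`` is the affected span for DEL/DUP/INV and the inserted length
    for INS; TRA uses ``(chrom, pos)`` and ``(chrom2, pos2)`` as the
    reciprocal exchange points and ignores ``length``.  ``copies`` is the
    number of *extra* tandem copies for DUP.
    """

    svtype: str
    chrom: str
    pos: int
    length: int = 0
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    copies: int = 1


@dataclass(frozen=True)
class Block:
    """A donor segment: a reference slice (strand -1 = reverse-complemented)
    or novel sequence (``ref_chrom is None``)."""

    ref_chrom: Optional[str]
    ref_start: int
    ref_end: int
    strand: int = 1
    novel_seq: Optional[str] = None

    @property
    def length(self) -> int:
        if self.ref_chrom is None:
            return len(self.novel_seq or "")
        return self.ref_end - self.ref_start


@dataclass
class TruthSV:
    sv_id: str
    svtype: str
    chrom: str
    pos: int
    end: Optional[int]
    length: int
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    copies: int = 1
    breakpoints: list = field(default_factory=list)  # [(chrom, pos), ...]


@dataclass
class TruthManifest:
    """Ground truth of a simulation: implanted SVs and the donor block map."""

    reference_lengths: dict
    svs: list
    blocks: dict  # donor chrom -> list[Block]

    @property
    def donor_lengths(self) -> dict:
        return {c: sum(b.length for b in bl) for c, bl in self.blocks.items()}


class OverlappingSpecsError(ValueError):
    pass


def make_reference(
    n_chroms: int = 2,
    lengths: Iterable[int] = (2_000_000, 2_000_000),
    seed: int = 0,
) -> dict[str, str]:
    """I.i.d. uniform ACGT chromosomes, reproducible from the seed."""
    lengths = list(lengths)
    if len(lengths) != n_chroms:
        raise ValueError("need one length per chromosome")
    rng = np.random.default_rng(seed)
    out = {}
    for i, L in enumerate(lengths, start=1):
        out[f"chr{i}"] = rng.choice(_BASES, size=L).tobytes().decode()
    return out


def _event_footprints(spec: SVSpec) -> list[tuple[str, int, int]]:
    if spec.svtype == "TRA":
        return [(spec.chrom, spec.pos, spec.pos + 1), (spec.chrom2, spec.pos2, spec.pos2 + 1)]
    if spec.svtype == "INS":
        return [(spec.chrom, spec.pos, spec.pos + 1)]
    return [(spec.chrom, spec.pos, spec.pos + spec.length)]


def _check_nonoverlapping(specs: list[SVSpec]) -> None:
    per_chrom: dict[str, list[tuple[int, int, SVSpec]]] = {}
    for s in specs:
        for chrom, a, b in _event_footprints(s):
            per_chrom.setdefault(chrom, []).append((a, b, s))
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        for (a1, b1, s1), (a2, b2, s2) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise OverlappingSpecsError(
                    f"overlapping SV specs on {chrom}: "
                    f"{s1.svtype}@{a1}-{b1} conflicts with {s2.svtype}@{a2}-{b2}"
                )


def apply_svs(
    reference: dict[str, str], specs: list[SVSpec], seed: int = 0
) -> tuple[dict[str, str], TruthManifest]:
    """Build the rearranged donor genome and its truth manifest.

    Returns ``(donor_sequences, manifest)``; the manifest records each SV's
    reference-coordinate breakpoints and the donor block map used for
    read liftover.
    """
    specs = list(specs)
    _check_nonoverlapping(specs)
    rng = np.random.default_rng(seed ^ 0x5F5F)
    blocks: dict[str, list[Block]] = {}
    svs: list[TruthSV] = []

    intra = [s for s in specs if s.svtype != "TRA"]
    tras = [s for s in specs if s.svtype == "TRA"]

    for chrom, seq in reference.items():
        events = sorted((s for s in intra if s.chrom == chrom), key=lambda s: s.pos)
        bl: list[Block] = []
        cursor = 0
        L = len(seq)
        for ev in events:
            if not 0 <= ev.pos <= L or (ev.svtype != "INS" and ev.pos + ev.length > L):
                raise ValueError(f"SV {ev} outside chromosome {chrom} (length {L})")
            if ev.pos > cursor:
                bl.append(Block(chrom, cursor, ev.pos))
            if ev.svtype == "DEL":
                cursor = ev.pos + ev.length
            elif ev.svtype == "DUP":
                for _ in range(ev.copies + 1):
                    bl.append(Block(chrom, ev.pos, ev.pos + ev.length))
                cursor = ev.pos + ev.length
            elif ev.svtype == "INV":
                bl.append(Block(chrom, ev.pos, ev.pos + ev.length, strand=-1))
                cursor = ev.pos + ev.length
            elif ev.svtype == "INS":
                novel = rng.choice(_BASES, size=ev.length).tobytes().decode()
                bl.append(Block(None, 0, 0, novel_seq=novel))
                cursor = ev.pos
            else:
                raise ValueError(f"unknown SV type {ev.svtype!r}")
        if cursor < L:
            bl.append(Block(chrom, cursor, L))
        blocks[chrom] = bl

    for ev in tras:
        if ev.chrom2 is None or ev.pos2 is None:
            raise ValueError("TRA spec requires chrom2/pos2")
        head1, tail1 = _split_blocks(blocks[ev.chrom], ev.chrom, ev.pos)
        head2, tail2 = _split_blocks(blocks[ev.chrom2], ev.chrom2, ev.pos2)
        blocks[ev.chrom] = head1 + tail2
        blocks[ev.chrom2] = head2 + tail1

    for i, s in enumerate(specs):
        if s.svtype == "TRA":
            bps = [(s.chrom, s.pos), (s.chrom2, s.pos2)]
            end = None
        elif s.svtype == "INS":
            bps = [(s.chrom, s.pos)]
            end = s.pos
        else:
            bps = [(s.chrom, s.pos), (s.chrom, s.pos + s.length)]
            end = s.pos + s.length
        svs.append(
            TruthSV(
                sv_id=f"sv{i + 1}",
                svtype=s.svtype,
                chrom=s.chrom,
                pos=s.pos,
                end=end,
                length=s.length,
                chrom2=s.chrom2,
                pos2=s.pos2,
                copies=s.copies,
                breakpoints=bps,
            )
        )

    donor = {
        chrom: "".join(
            (b.novel_seq if b.ref_chrom is None
             else reference[b.ref_chrom][b.ref_start:b.ref_end] if b.strand == 1
             else revcomp(reference[b.ref_chrom][b.ref_start:b.ref_end]))
            for b in bl
        )
        for chrom, bl in blocks.items()
    }
    manifest = TruthManifest(
        reference_lengths={c: len(s) for c, s in reference.items()},
        svs=svs,
        blocks=blocks,
    )
    return donor, manifest


def _split_blocks(bl: list[Block], chrom: str, ref_pos: int) -> tuple[list[Block], list[Block]]:
    offset = 0
    for i, b in enumerate(bl):
        if (
            b.ref_chrom == chrom
            and b.strand == 1
            and b.ref_start <= ref_pos < b.ref_end
        ):
            head = bl[:i]
            if ref_pos > b.ref_start:
                head = head + [Block(chrom, b.ref_start, ref_pos)]
            tail = [Block(chrom, ref_pos, b.ref_end)] + bl[i + 1:]
            return head, tail
        offset += b.length
    raise ValueError(
        f"translocation point {chrom}:{ref_pos} does not fall in unrearranged sequence"
    )


def expected_signature(svtype: str, library_orientation: str) -> dict:
    """The discordant read signature pairs spanning this SV type should show.

    Returns a dict with keys ``orientations`` (set of coordinate-order
    orientation strings) and ``insert`` (``"large"``, ``"small"``,
    ``"inter"`` or ``None``).
    """
    e1, e2 = strands_of(library_orientation)
    concordant = library_orientation
    everted = {("+", "-"): "RF", ("-", "+"): "FR"}[(e1, e2)]
    return {
        "DEL": {"orientations": {concordant}, "insert": "large"},
        "INS": {"orientations": {concordant}, "insert": "small"},
        "DUP": {"orientations": {everted}, "insert": None},
        "INV": {"orientations": {"FF", "RR"}, "insert": None},
        "TRA": {"orientations": None, "insert": "inter"},
    }[svtype]


def sample_pairs(
    manifest: TruthManifest,
    coverage: float,
    insert_mean: float = 3000.0,
    insert_sd: float = 300.0,
    read_len: int = 50,
    orientation: str = "RF",
    error_rate: float = 0.005,
    seed: int = 0,
    with_seqs: bool = False,
    donor_seqs: Optional[dict[str, str]] = None,
) -> list[ReadPairRecord]:
    """Draw paired reads from the donor and lift them to reference coordinates.

    Fragments are uniform on the donor with insert ~ Normal(mean, sd)
    truncated at ``2 * read_len``; reads sit at the fragment ends with the
    requested library orientation (FR paired-end or RF mate-pair).  Each
    read is placed at its exact reference mapping via the block map; pairs
    with a read crossing a junction or landing in novel sequence are
    dropped.  Returned records are sorted by ``(chrom1, alpha)`` in
    reference-contig order; ``pair_id`` ends in ``:S`` for SV-spanning
    pairs (mates in different donor blocks) and ``:B`` for background.

    With ``with_seqs`` the read sequences (donor bases with i.i.d.
    substitution errors at ``error_rate``, stored on the reference forward
    strand) are attached; this needs ``donor_seqs``.
    """
    if insert_mean <= 2 * read_len:
        raise ValueError("insert_mean must exceed twice the read length")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if with_seqs and donor_seqs is None:
        raise ValueError("with_seqs requires donor_seqs")
    rng = np.random.default_rng(seed)
    ref_names = list(manifest.reference_lengths)
    ref_index = {c: i for i, c in enumerate(ref_names)}
    r1_fwd = orientation == "FR"  # else RF: leftmost read sequenced on '-'

    cols: dict[str, list] = {k: [] for k in (
        "c1", "c2", "alpha", "beta", "s1", "s2", "ins", "span", "dchrom", "d1", "d2", "rev1", "rev2"
    )}

    for dchrom, bl in manifest.blocks.items():
        L = sum(b.length for b in bl)
        n = int(round(coverage * L / (2.0 * read_len)))
        if n == 0 or L < insert_mean:
            continue
        b_dstart = np.cumsum([0] + [b.length for b in bl][:-1]).astype(np.int64)
        b_len = np.array([b.length for b in bl], dtype=np.int64)
        # prefix count of *non-collinear* block boundaries: a fragment is
        # SV-junction-spanning only if its mates straddle one of those
        # (e.g. the flank -> first-copy boundary of a tandem DUP is
        # reference-collinear and produces perfectly concordant pairs)
        ncb = np.zeros(len(bl), dtype=np.int64)
        for i in range(1, len(bl)):
            a_, b_ = bl[i - 1], bl[i]
            collinear = (
                a_.ref_chrom is not None
                and a_.ref_chrom == b_.ref_chrom
                and a_.strand == b_.strand
                and (
                    (a_.strand == 1 and a_.ref_end == b_.ref_start)
                    or (a_.strand == -1 and a_.ref_start == b_.ref_end)
                )
            )
            ncb[i] = ncb[i - 1] + (0 if collinear else 1)
        b_refc = np.array(
            [ref_index[b.ref_chrom] if b.ref_chrom is not None else -1 for b in bl],
            dtype=np.int64,
        )
        b_rs = np.array([b.ref_start for b in bl], dtype=np.int64)
        b_re = np.array([b.ref_end for b in bl], dtype=np.int64)
        b_strand = np.array([b.strand for b in bl], dtype=np.int64)

        ins = np.rint(rng.normal(insert_mean, insert_sd, size=n)).astype(np.int64)
        ins = np.maximum(ins, 2 * read_len)
        ok = ins < L
        ins = ins[ok]
        starts = rng.integers(0, L - ins + 1)
        r1 = starts
        r2 = starts + ins - read_len

        def _map(s):
            bi = np.searchsorted(b_dstart, s, side="right") - 1
            within = (s + read_len) <= (b_dstart[bi] + b_len[bi])
            mapped = b_refc[bi] >= 0
            off = s - b_dstart[bi]
            pos = np.where(
                b_strand[bi] == 1,
                b_rs[bi] + off,
                b_re[bi] - off - read_len,
            )
            return bi, pos, b_refc[bi], (b_strand[bi] == -1), within & mapped

        bi1, p1, c1, flip1, ok1 = _map(r1)
        bi2, p2, c2, flip2, ok2 = _map(r2)
        keep = ok1 & ok2
        bi1, p1, c1, flip1 = bi1[keep], p1[keep], c1[keep], flip1[keep]
        bi2, p2, c2, flip2 = bi2[keep], p2[keep], c2[keep], flip2[keep]
        d1, d2 = r1[keep], r2[keep]

        # sequenced (donor) strands by library chemistry, then block flips
        st1 = np.full(p1.shape, not r1_fwd)  # True = reverse
        st2 = np.full(p2.shape, r1_fwd)
        rs1 = st1 ^ flip1
        rs2 = st2 ^ flip2

        first = (c1 < c2) | ((c1 == c2) & (p1 <= p2))
        a = np.where(first, p1, p2)
        b = np.where(first, p2, p1)
        ca = np.where(first, c1, c2)
        cb = np.where(first, c2, c1)
        sa = np.where(first, rs1, rs2)
        sb = np.where(first, rs2, rs1)
        same = ca == cb
        isz = np.where(same, b + read_len - a, -1)
        span = ncb[bi1] != ncb[bi2]

        cols["c1"].append(ca)
        cols["c2"].append(cb)
        cols["alpha"].append(a)
        cols["beta"].append(b)
        cols["s1"].append(sa)
        cols["s2"].append(sb)
        cols["ins"].append(isz)
        cols["span"].append(span)
        cols["dchrom"].append(np.full(a.shape, list(manifest.blocks).index(dchrom)))
        cols["d1"].append(np.where(first, d1, d2))
        cols["d2"].append(np.where(first, d2, d1))
        cols["rev1"].append(np.where(first, flip1, flip2))
        cols["rev2"].append(np.where(first, flip2, flip1))

    if not cols["c1"]:
        return []
    arr = {k: np.concatenate(v) for k, v in cols.items()}
    order = np.lexsort((arr["alpha"], arr["c1"]))
    dchrom_names = list(manifest.blocks)

    seqs1 = seqs2 = None
    if with_seqs:
        seqs1, seqs2 = _extract_seqs(arr, order, dchrom_names, donor_seqs,
                                     read_len, error_rate, rng)

    records: list[ReadPairRecord] = []
    c1 = arr["c1"]; c2 = arr["c2"]; al = arr["alpha"]; be = arr["beta"]
    s1 = arr["s1"]; s2 = arr["s2"]; isz = arr["ins"]; span = arr["span"]
    dch = arr["dchrom"]
    for j, i in enumerate(order.tolist()):
        records.append(
            ReadPairRecord(
                pair_id=f"{dchrom_names[dch[i]]}:{i}:{'S' if span[i] else 'B'}",
                chrom1=ref_names[c1[i]],
                chrom2=ref_names[c2[i]],
                alpha=int(al[i]),
                beta=int(be[i]),
                strand1="-" if s1[i] else "+",
                strand2="-" if s2[i] else "+",
                insert_size=int(isz[i]) if isz[i] >= 0 else None,
                seq1=seqs1[j] if seqs1 is not None else None,
                seq2=seqs2[j] if seqs2 is not None else None,
            )
        )
    return records


def _extract_seqs(arr, order, dchrom_names, donor_seqs, read_len, error_rate, rng):
    """Reference-forward-strand read sequences with substitution errors."""
    seqs1, seqs2 = [], []
    bases = "ACGT"
    for i in order.tolist():
        donor = donor_seqs[dchrom_names[arr["dchrom"][i]]]
        for key_d, key_rev, out in (("d1", "rev1", seqs1), ("d2", "rev2", seqs2)):
            s = int(arr[key_d][i])
            sub = donor[s:s + read_len]
            if error_rate > 0:
                n_err = rng.binomial(read_len, error_rate)
                if n_err:
                    seq = list(sub)
                    for p in rng.integers(0, read_len, size=n_err):
                        seq[p] = bases[(bases.index(seq[p].upper()) + 1 + rng.integers(0, 3)) % 4]
                    sub = "".join(seq)
            out.append(revcomp(sub) if arr[key_rev][i] else sub)
    return seqs1, seqs2


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_sam(
    records: list[ReadPairRecord],
    contigs: list[tuple[str, int]],
    path: str,
    read_len: int = 50,
) -> None:
    """Write pairs as a coordinate-sorted SAM with correct mate/flag fields."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": int(l)} for n, l in contigs],
    }
    tid = {n: i for i, (n, _) in enumerate(contigs)}
    rows = []
    for rec in records:
        same = rec.chrom1 == rec.chrom2
        tlen = (rec.insert_size or 0) if same else 0
        for which in (1, 2):
            if which == 1:
                chrom, pos, rev = rec.chrom1, rec.alpha, rec.strand1 == "-"
                mchrom, mpos, mrev = rec.chrom2, rec.beta, rec.strand2 == "-"
                my_tlen, seq = tlen, rec.seq1
            else:
                chrom, pos, rev = rec.chrom2, rec.beta, rec.strand2 == "-"
                mchrom, mpos, mrev = rec.chrom1, rec.alpha, rec.strand1 == "-"
                my_tlen, seq = -tlen, rec.seq2
            flag = 0x1 | (0x40 if which == 1 else 0x80)
            if rev:
                flag |= 0x10
            if mrev:
                flag |= 0x20
            if rec.is_duplicate:
                flag |= 0x400
            rows.append((tid[chrom], pos, rec.pair_id, flag, chrom, mchrom, mpos,
                         my_tlen, seq))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for tid_, pos, qname, flag, chrom, mchrom, mpos, tlen_, seq in rows:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = tid_
            a.reference_start = int(pos)
            a.mapping_quality = 60
            a.cigarstring = f"{read_len}M"
            a.next_reference_id = tid[mchrom]
            a.next_reference_start = int(mpos)
            a.template_length = int(tlen_)
            if seq is not None:
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)


def write_truth(manifest: TruthManifest, bedpe_path: str, json_path: str) -> None:
    """Truth BEDPE (one row per SV, breakpoints as 1 bp intervals) + JSON."""
    with open(bedpe_path, "w") as fh:
        for sv in manifest.svs:
            bps = sv.breakpoints
            (c1, p1) = bps[0]
            (c2, p2) = bps[-1]
            fh.write(
                f"{c1}\t{p1}\t{p1 + 1}\t{c2}\t{p2}\t{p2 + 1}\t"
                f"{sv.sv_id}\t{sv.svtype}\t.\t.\n"
            )
    payload = {
        "reference_lengths": manifest.reference_lengths,
        "svs": [asdict(sv) for sv in manifest.svs],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class Scenario:
    """A complete simulation configuration.

    The default scenario is the package's standard study condition: two 2 Mb
    chromosomes carrying five SVs of 5-20 kb (2 DEL, 1 tandem DUP, 1 INV,
    1 reciprocal TRA), sequenced at 30x as an RF mate-pair library with
    3000 +/- 300 bp inserts, 50 bp reads and 0.5% substitution errors.
    """

    chrom_lengths: tuple = (2_000_000, 2_000_000)
    specs: tuple = (
        SVSpec("DEL", "chr1", 200_000, 10_000),
        SVSpec("DUP", "chr1", 600_000, 10_000, copies=1),
        SVSpec("INV", "chr1", 1_200_000, 12_000),
        SVSpec("DEL", "chr2", 300_000, 8_000),
        SVSpec("TRA", "chr1", 1_700_000, chrom2="chr2", pos2=1_400_000),
    )
    coverage: float = 30.0
    insert_mean: float = 3000.0
    insert_sd: float = 300.0
    read_len: int = 50
    orientation: str = "RF"
    error_rate: float = 0.005


def default_scenario() -> Scenario:
    return Scenario()


@dataclass
class SimResult:
    reference: dict
    donor: dict
    manifest: TruthManifest
    records: list
    contigs: list  # [(name, length), ...]
    scenario: Scenario


def simulate_scenario(
    scenario: Optional[Scenario] = None,
    seed: int = 0,
    with_seqs: bool = False,
) -> SimResult:
    """Run reference -> donor -> read sampling for a scenario in memory."""
    sc = scenario or default_scenario()
    ref = make_reference(len(sc.chrom_lengths), sc.chrom_lengths, seed=seed)
    donor, manifest = apply_svs(ref, list(sc.specs), seed=seed)
    records = sample_pairs(
        manifest,
        coverage=sc.coverage,
        insert_mean=sc.insert_mean,
        insert_sd=sc.insert_sd,
        read_len=sc.read_len,
        orientation=sc.orientation,
        error_rate=sc.error_rate,
        seed=seed + 1,
        with_seqs=with_seqs,
        donor_seqs=donor if with_seqs else None,
    )
    contigs = [(c, len(s)) for c, s in ref.items()]
    return SimResult(ref, donor, manifest, records, contigs, sc)
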