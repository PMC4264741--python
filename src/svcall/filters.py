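"""False-positive filters: local realignment rescue and repeat-track overlap.

Two independent mechanisms reduce artifact calls:

* **Realignment rescue** re-examines each discordant pair: if one of its
  reads aligns well (high identity over most of its length) inside the
  reference window where a *concordant* placement relative to the other
  mate would fall, the discordancy is a mapping artifact and the pair is
  discarded from the discordant set.  The alignment engine is affine-gap
  local (Smith-Waterman) pairwise alignment.

* **Annotation-track filters** score each variant call by the fraction of
  its interval covered by user-supplied BED tracks (segmental duplications,
  RepeatMasker, self-chain, ...) and tag or remove calls whose overlap
  exceeds a threshold, eliminating calls driven by aberrant mapping in
  repetitive sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

from Bio import Align
from intervaltree import IntervalTree

from .alignments import InsertSizeModel, ReadPairRecord
from ._util import revcomp, strands_of

__all__ = [
    "AnnotationTrack",
    "make_rescue_aligner",
    "realignment_rescue",
    "rescue_discordant",
    "overlap_fraction",
    "apply_track_filters",
]


class AnnotationTrack:
    """A named set of genomic intervals, queryable by overlap.

    Intervals are 0-based half-open; overlapping intervals are merged
    (union) on construction, so overlap fractions never double count.
    """

    def __init__(self, name: str, intervals: Iterable[tuple[str, int, int]]):
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"malformed interval {chrom}:{start}-{end}")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)

    @classmethod
    def from_bed(cls, path: str, name: Optional[str] = None) -> "AnnotationTrack":
        """Load a BED3+ file (extra columns ignored, track/browser lines skipped)."""
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                ivs.append((f[0], int(f[1]), int(f[2])))
        return cls(name or path, ivs)

    def overlap_bases(self, chrom: str, start: int, end: int) -> int:
        tree = self._trees.get(chrom)
        if tree is None:
            return 0
        return sum(
            min(iv.end, end) - max(iv.begin, start) for iv in tree.overlap(start, end)
        )

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def overlap_fraction(
    call_interval: tuple[str, int, int], track: AnnotationTrack
) -> float:
    """Fraction of ``call_interval`` bases covered by the track union."""
    chrom, start, end = call_interval
    if end <= start:
        raise ValueError(f"malformed call interval {chrom}:{start}-{end}")
    return track.overlap_bases(chrom, start, end) / (end - start)


def make_rescue_aligner() -> Align.PairwiseAligner:
    """Default affine-gap local aligner: match 1, mismatch -1, open -2, extend -1."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _identity_ok(aln, read_len: int, min_identity_frac: float) -> bool:
    counts = aln.counts()
    span = counts.identities + counts.mismatches
    if span < 0.9 * read_len:
        return False
    return counts.identities / span >= min_identity_frac


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    seq = reference[chrom]
    start = max(0, start)
    return str(seq[start:end])


def realignment_rescue(
    pair: ReadPairRecord,
    reference: Mapping[str, str],
    read_seqs: tuple[str, str],
    median_is: float,
    search_margin: float,
    min_identity_frac: float = 0.9,
    aligner: Optional[Align.PairwiseAligner] = None,
    expected_orientation: str = "FR",
) -> bool:
    """Decide whether a discordant pair survives local realignment.

    For each mate, its sequence is locally realigned against the reference
    window where a *concordant* placement relative to the other mate would
    fall: on the side the other mate points to, within the median insert
    size plus ``search_margin``, and on the strand that would restore the
    library's expected orientation (an alignment on the wrong strand is not
    a concordant placement, so genuine inversion-spanning pairs are not
    rescued away).  If either mate aligns there with identity >=
    ``min_identity_frac`` over >= 90% of its length, the discordancy is a
    mapping artifact: return ``False`` (discard).  Otherwise return ``True``.

    Read sequences are taken as stored in SAM, i.e. on the forward strand of
    the mate's current mapping.  Raises ``KeyError`` naming the contig if it
    is missing from the reference.
    """
    if aligner is None:
        aligner = make_rescue_aligner()
    e1, e2 = strands_of(expected_orientation)
    # (anchor chrom, anchor pos, anchor strand, query seq, query's current strand)
    sides = (
        (pair.chrom2, pair.beta, pair.strand2, read_seqs[0], pair.strand1),
        (pair.chrom1, pair.alpha, pair.strand1, read_seqs[1], pair.strand2),
    )
    margin = int(search_margin)
    reach = int(median_is) + margin
    for chrom, anchor, anchor_strand, seq, cur_strand in sides:
        if not seq:
            continue
        if chrom not in reference:
            raise KeyError(f"reference contig {chrom!r} not found")
        L = len(seq)
        if anchor_strand == e1:  # anchor points right: partner right of it, strand e2
            lo, hi = anchor - margin, anchor + reach + L
            required = e2
        else:  # anchor points left: partner left of it, strand e1
            lo, hi = anchor - reach, anchor + margin + L
            required = e1
        window = _fetch(reference, chrom, lo, hi)
        if len(window) < L:
            continue
        query = seq if cur_strand == required else revcomp(seq)
        # a qualifying alignment needs >= 0.9*L columns at >= min_id identity;
        # loose score bound skips hopeless windows cheaply
        alns = aligner.align(window, query)
        if alns.score < 0.45 * L * (2.0 * min_identity_frac - 1.0):
            continue
        try:
            best = alns[0]
        except IndexError:
            continue
        if _identity_ok(best, L, min_identity_frac):
            return False
    return True


def rescue_discordant(
    pairs: Iterable[ReadPairRecord],
    reference: Mapping[str, str],
    model: InsertSizeModel,
    search_margin: Optional[float] = None,
    min_identity_frac: float = 0.9,
) -> tuple[list[ReadPairRecord], int]:
    """Apply :func:`realignment_rescue` to a discordant set.

    Pairs without stored read sequences are kept unexamined.  Default
    ``search_margin`` is 4 sigma_IS.  Returns (kept pairs, number discarded).
    """
    if search_margin is None:
        search_margin = 4.0 * model.sigma_is
    aligner = make_rescue_aligner()
    kept: list[ReadPairRecord] = []
    discarded = 0
    for p in pairs:
        if p.seq1 is None or p.seq2 is None:
            kept.append(p)
            continue
        if realignment_rescue(
            p, reference, (p.seq1, p.seq2), model.median_is,
            search_margin, min_identity_frac, aligner,
            expected_orientation=model.expected_orientation,
        ):
            kept.append(p)
        else:
            discarded += 1
    return kept, discarded


def apply_track_filters(
    calls: list,
    tracks: list[AnnotationTrack],
    max_frac: Union[float, Mapping[str, float]] = 0.5,
    mode: str = "annotate",
) -> list:
    """Score SV calls against annotation tracks and tag/remove heavy overlaps.

    Every call gains per-track overlap fractions (``call.track_overlaps``)
    and a ``<track>_overlap`` filter tag where the fraction exceeds the
    track's threshold.  ``mode="annotate"`` (default) never removes calls;
    ``mode="remove"`` drops tagged ones.  Intra-chromosomal calls are scored
    on their full span; two-sided calls (TRA) on each breakpoint confidence
    interval, tagging if *either* side exceeds the threshold.
    """
    if mode not in ("annotate", "remove"):
        raise ValueError(f"unknown filter mode {mode!r}")
    out = []
    for call in calls:
        intervals = _call_intervals(call)
        tagged = False
        for track in tracks:
            thr = max_frac.get(track.name, 0.5) if isinstance(max_frac, Mapping) else max_frac
            if not 0.0 <= thr <= 1.0:
                raise ValueError(f"threshold for track {track.name!r} outside [0, 1]")
            frac = max(overlap_fraction(iv, track) for iv in intervals)
            call.track_overlaps[track.name] = frac
            if frac > thr:
                tag = f"{track.name}_overlap"
                if tag not in call.filters:
                    call.filters.append(tag)
                tagged = True
        if mode == "annotate" or not tagged:
            out.append(call)
    return out


def _call_intervals(call) -> list[tuple[str, int, int]]:
    """Intervals on which a call's repeat overlap is evaluated."""
    if call.chrom1 != call.chrom2:
        return [
            (call.chrom1, call.ci1[0], max(call.ci1[1], call.ci1[0] + 1)),
            (call.chrom2, call.ci2[0], max(call.ci2[1], call.ci2[0] + 1)),
        ]
    lo, hi = sorted((call.pos1, call.pos2))
    if hi <= lo:
        hi = lo + 1
    return [(call.chrom1, lo, hi)]
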