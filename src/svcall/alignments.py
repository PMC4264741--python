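"""Mate-pair ingestion, insert-size modelling and discordancy classification.

A coordinate-sorted SAM/BAM of paired reads is reduced to one
:class:`ReadPairRecord` per primary pair.  From the same-chromosome pairs an
:class:`InsertSizeModel` is estimated (median insert size and a robust scale
estimate sigma_IS), and every pair is then classified as concordant or
discordant with an explicit reason set (large/small insert, unexpected
orientation, inter-chromosomal).

Coordinates are 0-based, half-open throughout.  The insert size is the
*outer* distance between the two mates (rightmost end minus leftmost start);
it is recomputed from the mate positions rather than taken from TLEN, whose
sign/anchor conventions vary between aligners.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pysam
from scipy import stats as _scipy_stats

from ._util import orientation_of

__all__ = [
    "ReadPairRecord",
    "InsertSizeModel",
    "DiscordancyCall",
    "LoadStats",
    "UnsortedInputError",
    "InsertModelError",
    "load_read_pairs",
    "estimate_insert_model",
    "classify_pair",
]


class UnsortedInputError(ValueError):
    """Raised when the input alignment file is not coordinate-sorted."""


class InsertModelError(ValueError):
    """Raised when the insert-size model cannot be estimated reliably."""


@dataclass(slots=True)
class ReadPairRecord:
    """One aligned mate pair, mates in coordinate order.

    ``alpha`` is the leftmost mapping position of the first-in-coordinate-order
    mate and ``beta`` that of the second; on a single chromosome
    ``alpha <= beta`` always holds.  ``insert_size`` is the outer distance and
    is ``None`` for inter-chromosomal pairs.
    """

    pair_id: str
    chrom1: str
    chrom2: str
    alpha: int
    beta: int
    strand1: str
    strand2: str
    insert_size: Optional[int]
    mapq1: int = 60
    mapq2: int = 60
    is_duplicate: bool = False
    seq1: Optional[str] = None
    seq2: Optional[str] = None

    @property
    def orientation(self) -> str:
        """Relative orientation in coordinate order: FR, RF, FF or RR."""
        return orientation_of(self.strand1, self.strand2)

    @property
    def is_interchromosomal(self) -> bool:
        return self.chrom1 != self.chrom2


@dataclass(slots=True)
class InsertSizeModel:
    """Library insert-size model used to flag discordant pairs.

    ``sigma_is`` is the scale of the insert-size distribution over all sampled
    same-chromosome pairs; by default it is the robust estimate
    1.4826 x MAD so that SV-generated outliers do not inflate it.  A pair is
    insert-discordant when its insert size falls outside
    ``median_is +/- k_discordant * sigma_is``.
    """

    median_is: float
    sigma_is: float
    expected_orientation: str
    k_discordant: float = 3.0
    n_pairs_sampled: int = 0

    @property
    def upper_insert(self) -> float:
        return self.median_is + self.k_discordant * self.sigma_is

    @property
    def lower_insert(self) -> float:
        # floored at 0: insert sizes are non-negative by construction
        return max(0.0, self.median_is - self.k_discordant * self.sigma_is)


@dataclass(slots=True)
class DiscordancyCall:
    status: str  # "concordant" | "discordant"
    reasons: frozenset = frozenset()

    def __post_init__(self):
        if self.status == "discordant" and not self.reasons:
            raise ValueError("discordant call requires at least one reason")
        if self.status == "concordant" and self.reasons:
            raise ValueError("concordant call cannot carry reasons")

    @property
    def is_discordant(self) -> bool:
        return self.status == "discordant"


@dataclass
class LoadStats:
    """Side-channel counters filled in by :func:`load_read_pairs`."""

    n_pairs: int = 0
    n_orphans: int = 0
    n_duplicates_skipped: int = 0
    n_low_mapq: int = 0
    n_secondary_skipped: int = 0
    read_length: int = 0
    contigs: dict = field(default_factory=dict)


def _pair_from_mates(qname, m1, m2) -> ReadPairRecord:
    """Build a record from two (tid, chrom, pos, end, strand, mapq, dup, seq) mates."""
    a, b = sorted((m1, m2), key=lambda m: (m[0], m[2]))
    same = a[1] == b[1]
    insert = (max(a[3], b[3]) - a[2]) if same else None
    return ReadPairRecord(
        pair_id=qname,
        chrom1=a[1],
        chrom2=b[1],
        alpha=a[2],
        beta=b[2],
        strand1=a[4],
        strand2=b[4],
        insert_size=insert,
        mapq1=a[5],
        mapq2=b[5],
        is_duplicate=a[6] or b[6],
        seq1=a[7],
        seq2=b[7],
    )


def load_read_pairs(
    path: str,
    min_mapq: int = 20,
    drop_duplicates: bool = True,
    stats: Optional[LoadStats] = None,
    keep_seqs: bool = False,
) -> list[ReadPairRecord]:
    """Read a coordinate-sorted SAM/BAM and reconstruct primary mate pairs.

    Only pairs where both mates are mapped in a primary alignment with
    ``mapq >= min_mapq`` are emitted (mapq 0 marks non-unique placements and
    is excluded by the default threshold).  Secondary/supplementary
    alignments are skipped; duplicate-flagged pairs are skipped when
    ``drop_duplicates`` is set.  Orphan mates are counted in ``stats`` and
    not emitted.  Returns records sorted by ``(chrom1, alpha)`` in the
    file's contig order.

    Raises :class:`UnsortedInputError` naming the first out-of-order record.
    """
    if stats is None:
        stats = LoadStats()
    mates: dict[str, tuple] = {}
    pairs: list[ReadPairRecord] = []
    read_lengths: Counter = Counter()
    tid_order: dict[str, int] = {}

    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for i, name in enumerate(fh.references):
            tid_order[name] = i
            stats.contigs[name] = fh.lengths[i]
        last = (-1, -1, "")
        for aln in fh:
            if aln.is_unmapped:
                continue
            if aln.is_secondary or aln.is_supplementary:
                stats.n_secondary_skipped += 1
                continue
            key = (aln.reference_id, aln.reference_start)
            if key < last[:2]:
                raise UnsortedInputError(
                    f"input is not coordinate-sorted: read {aln.query_name!r} at "
                    f"{aln.reference_name}:{aln.reference_start} follows "
                    f"{last[2]!r} at tid {last[0]}:{last[1]}"
                )
            last = (*key, aln.query_name)
            if aln.query_length:
                read_lengths[aln.query_length] += 1
            mate = (
                aln.reference_id,
                aln.reference_name,
                aln.reference_start,
                aln.reference_end or aln.reference_start,
                "-" if aln.is_reverse else "+",
                aln.mapping_quality,
                aln.is_duplicate,
                aln.query_sequence if keep_seqs else None,
            )
            other = mates.pop(aln.query_name, None)
            if other is None:
                mates[aln.query_name] = mate
                continue
            rec = _pair_from_mates(aln.query_name, other, mate)
            if rec.is_duplicate and drop_duplicates:
                stats.n_duplicates_skipped += 1
                continue
            if min(rec.mapq1, rec.mapq2) < min_mapq:
                stats.n_low_mapq += 1
                continue
            pairs.append(rec)

    stats.n_orphans = len(mates)
    stats.n_pairs = len(pairs)
    if read_lengths:
        stats.read_length = read_lengths.most_common(1)[0][0]
    pairs.sort(key=lambda r: (tid_order.get(r.chrom1, 1 << 30), r.chrom1, r.alpha))
    return pairs


def estimate_insert_model(
    pairs: Iterable[ReadPairRecord],
    k_discordant: float = 3.0,
    max_sample: int = 1_000_000,
    min_pairs: int = 50,
    robust: bool = True,
) -> InsertSizeModel:
    """Estimate the insert-size model from same-chromosome pairs.

    The modal relative orientation over the sample defines the library's
    expected orientation (FR for short-insert paired-end, RF for circularised
    mate-pair libraries).  ``median_is`` is the median insert of
    majority-orientation pairs and ``sigma_is`` their robust scale
    (1.4826 x MAD, floored at 1 bp); ``robust=False`` restores the plain
    standard deviation.
    """
    orient_counts: Counter = Counter()
    sampled: list[tuple[str, int]] = []
    for rec in pairs:
        if rec.is_interchromosomal or rec.insert_size is None:
            continue
        orient_counts[rec.orientation] += 1
        sampled.append((rec.orientation, rec.insert_size))
        if len(sampled) >= max_sample:
            break
    if not sampled:
        raise InsertModelError("no same-chromosome pairs to estimate insert model from")
    expected = orient_counts.most_common(1)[0][0]
    inserts = np.array([i for o, i in sampled if o == expected], dtype=float)
    if inserts.size < min_pairs:
        raise InsertModelError(
            f"only {inserts.size} usable pairs (< {min_pairs}); the discordancy "
            "thresholds cannot be estimated reliably"
        )
    median = float(np.median(inserts))
    if robust:
        sigma = float(_scipy_stats.median_abs_deviation(inserts, scale="normal"))
    else:
        sigma = float(np.std(inserts, ddof=1))
    sigma = max(sigma, 1.0)  # degenerate spread floor
    return InsertSizeModel(
        median_is=median,
        sigma_is=sigma,
        expected_orientation=expected,
        k_discordant=k_discordant,
        n_pairs_sampled=int(inserts.size),
    )


def classify_pair(pair: ReadPairRecord, model: InsertSizeModel) -> DiscordancyCall:
    """Classify one pair against the insert-size model.

    Total over valid records: every pair is either concordant or discordant
    with a non-empty reason set.  Reasons combine (e.g. a pair can be both
    orientation- and insert-discordant).
    """
    reasons = set()
    if pair.chrom1 != pair.chrom2:
        reasons.add("inter_chromosomal")
    else:
        if pair.orientation != model.expected_orientation:
            reasons.add("orientation")
        ins = pair.insert_size
        if ins is not None:
            if ins > model.upper_insert:
                reasons.add("large_insert")
            elif ins < model.lower_insert:
                reasons.add("small_insert")
    if reasons:
        return DiscordancyCall("discordant", frozenset(reasons))
    return DiscordancyCall("concordant")


def split_by_discordancy(
    pairs: Iterable[ReadPairRecord], model: InsertSizeModel
) -> tuple[list[ReadPairRecord], list[ReadPairRecord]]:
    """Partition a pair stream into (concordant, discordant) lists."""
    conc: list[ReadPairRecord] = []
    disc: list[ReadPairRecord] = []
    upper = model.upper_insert
    lower = model.lower_insert
    expected = model.expected_orientation
    for rec in pairs:
        if rec.chrom1 != rec.chrom2:
            disc.append(rec)
        elif rec.orientation != expected:
            disc.append(rec)
        elif rec.insert_size is not None and not (lower <= rec.insert_size <= upper):
            disc.append(rec)
        else:
            conc.append(rec)
    return conc, disc
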