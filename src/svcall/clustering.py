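"""Hard clustering of discordant pairs and breakpoint-interval derivation.

Discordant pairs are streamed sorted by ``(chrom1, alpha)`` and grouped into
clusters of pairs with similar first-read position, second-read position,
insert size and identical strand signature.  The similarity window on each
coordinate is +/- 2 sigma_IS around the cluster's running mean.  Each pair
joins at most one cluster — the closest matching one in the (alpha, beta)
plane — or seeds a new cluster.  Clusters whose running alpha mean has
fallen more than 2 sigma_IS behind the scan position can no longer accept
members and are closed, which bounds memory without changing the result.

After clustering, a coverage-dependent minimum-support cutoff removes
clusters with too few pairs to evidence a breakpoint, and each surviving
cluster yields two breakpoint intervals (one per side) guaranteed, up to the
insert-size model, to contain the true junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .alignments import InsertSizeModel, ReadPairRecord
from ._util import strands_of

__all__ = [
    "DiscordantCluster",
    "BreakpointInterval",
    "is_member",
    "cluster_discordant",
    "min_support_cutoff",
    "filter_by_support",
    "breakpoint_intervals",
    "write_bedpe",
]


@dataclass
class DiscordantCluster:
    """A group of similar discordant pairs supporting one junction."""

    cluster_id: str
    chrom1: str
    chrom2: str
    strand1: str
    strand2: str
    mu_alpha: float
    mu_beta: float
    mu_is: Optional[float]  # None for inter-chromosomal clusters
    alphas: list[int] = field(default_factory=list)
    betas: list[int] = field(default_factory=list)
    member_ids: list[str] = field(default_factory=list)
    _index: int = 0  # creation order, used for deterministic tie-breaking

    @property
    def support(self) -> int:
        return len(self.member_ids)

    @property
    def strand_signature(self) -> tuple[str, str]:
        return (self.strand1, self.strand2)

    def add(self, pair: ReadPairRecord, freeze_means: bool = False) -> None:
        self.alphas.append(pair.alpha)
        self.betas.append(pair.beta)
        self.member_ids.append(pair.pair_id)
        if not freeze_means:
            n = len(self.member_ids)
            self.mu_alpha += (pair.alpha - self.mu_alpha) / n
            self.mu_beta += (pair.beta - self.mu_beta) / n
            if self.mu_is is not None and pair.insert_size is not None:
                self.mu_is += (pair.insert_size - self.mu_is) / n


@dataclass(frozen=True)
class BreakpointInterval:
    """0-based half-open region containing a putative breakpoint."""

    chrom: str
    lo: int
    hi: int

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValueError(f"empty breakpoint interval [{self.lo}, {self.hi})")

    def __contains__(self, pos: int) -> bool:
        return self.lo <= pos < self.hi

    @property
    def mid(self) -> int:
        return (self.lo + self.hi) // 2


def is_member(pair: ReadPairRecord, cluster: DiscordantCluster, sigma_is: float) -> bool:
    """Similarity test for joining ``pair`` to ``cluster``.

    True iff both read positions fall within 2 sigma_IS of the cluster's
    running means, the strand signature matches, and (same-chromosome pairs
    only) the insert size is within 2 sigma_IS of the cluster's running mean
    insert size.
    """
    if (pair.chrom1, pair.chrom2) != (cluster.chrom1, cluster.chrom2):
        return False
    if (pair.strand1, pair.strand2) != (cluster.strand1, cluster.strand2):
        return False
    w = 2.0 * sigma_is
    if abs(pair.alpha - cluster.mu_alpha) > w:
        return False
    if abs(pair.beta - cluster.mu_beta) > w:
        return False
    if cluster.mu_is is not None and pair.insert_size is not None:
        if abs(pair.insert_size - cluster.mu_is) > w:
            return False
    return True


def cluster_discordant(
    pairs: Iterable[ReadPairRecord],
    model: InsertSizeModel,
    freeze_means: bool = False,
) -> list[DiscordantCluster]:
    """Stream sorted discordant pairs into hard clusters.

    Every pair belongs to exactly one cluster: among open clusters passing
    :func:`is_member` it joins the one minimising the Euclidean distance
    sqrt((alpha - mu_alpha)^2 + (beta - mu_beta)^2) (ties broken by creation
    order); otherwise it seeds a new cluster at (alpha, beta).  Singletons
    are clusters of support 1 and are removed later by the support filter.

    ``freeze_means`` keeps cluster centroids at their seed values instead of
    updating them incrementally after each addition.

    Input must be sorted by (chrom1, alpha); an unsorted stream raises
    ``ValueError``.  The result is deterministic.
    """
    sigma = model.sigma_is
    horizon = 2.0 * sigma
    open_clusters: list[DiscordantCluster] = []
    closed: list[DiscordantCluster] = []
    all_clusters: list[DiscordantCluster] = []
    prev_key: Optional[tuple[str, int]] = None
    prev_chrom: Optional[str] = None
    finished_chroms: set[str] = set()

    for pair in pairs:
        key = (pair.chrom1, pair.alpha)
        if prev_key is not None and pair.chrom1 == prev_key[0] and pair.alpha < prev_key[1]:
            raise ValueError(
                f"discordant pair stream not sorted by (chrom1, alpha): "
                f"{pair.pair_id!r} at {pair.chrom1}:{pair.alpha} follows {prev_key}"
            )
        prev_key = key
        if pair.chrom1 != prev_chrom:
            if pair.chrom1 in finished_chroms:
                raise ValueError(
                    f"discordant pair stream not grouped by chrom1: "
                    f"{pair.chrom1!r} reappears at pair {pair.pair_id!r}"
                )
            if prev_chrom is not None:
                finished_chroms.add(prev_chrom)
            # sorted by chrom1 first: clusters on other chromosomes are done
            closed.extend(c for c in open_clusters if c.chrom1 != pair.chrom1)
            open_clusters = [c for c in open_clusters if c.chrom1 == pair.chrom1]
            prev_chrom = pair.chrom1
        if open_clusters:
            limit = pair.alpha - horizon
            still_open = []
            for c in open_clusters:
                if c.mu_alpha < limit:
                    closed.append(c)
                else:
                    still_open.append(c)
            open_clusters = still_open

        best: Optional[DiscordantCluster] = None
        best_d = math.inf
        for c in open_clusters:
            if is_member(pair, c, sigma):
                d = math.hypot(pair.alpha - c.mu_alpha, pair.beta - c.mu_beta)
                if d < best_d:  # strict: earlier-created cluster wins ties
                    best, best_d = c, d
        if best is None:
            best = DiscordantCluster(
                cluster_id=f"c{len(all_clusters):06d}",
                chrom1=pair.chrom1,
                chrom2=pair.chrom2,
                strand1=pair.strand1,
                strand2=pair.strand2,
                mu_alpha=float(pair.alpha),
                mu_beta=float(pair.beta),
                mu_is=float(pair.insert_size)
                if (pair.chrom1 == pair.chrom2 and pair.insert_size is not None)
                else None,
                _index=len(all_clusters),
            )
            best.alphas.append(pair.alpha)
            best.betas.append(pair.beta)
            best.member_ids.append(pair.pair_id)
            open_clusters.append(best)
            all_clusters.append(best)
        else:
            best.add(pair, freeze_means=freeze_means)

    closed.extend(open_clusters)
    closed.sort(key=lambda c: c._index)
    return closed


def min_support_cutoff(mean_coverage: float, floor: int = 2) -> int:
    """Coverage-dependent minimum number of pairs required per cluster.

    For read-pair clusters the relevant coverage is the *physical* (fragment)
    coverage seen by the library; the cutoff is ``max(floor,
    round(mean_coverage / 10))``.
    """
    if mean_coverage < 0:
        raise ValueError(f"mean coverage must be non-negative, got {mean_coverage}")
    return max(int(floor), int(round(mean_coverage / 10.0)))


def filter_by_support(
    clusters: list[DiscordantCluster], min_support: int
) -> list[DiscordantCluster]:
    """Keep clusters with ``support >= min_support``; order preserved."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    return [c for c in clusters if c.support >= min_support]


def _side_interval(
    chrom: str,
    positions: list[int],
    strand: str,
    pointing_strand: str,
    mu: float,
    model: InsertSizeModel,
    read_len: int,
) -> BreakpointInterval:
    """Interval containing the junction implied by one side of a cluster.

    A read whose strand equals the library's leftmost-concordant-mate strand
    points *towards* its mate, so the junction lies to its right within one
    insert size; otherwise the junction lies to its left.  If the
    construction degenerates, fall back to a window of width 4 sigma_IS
    centred on the running mean (offset by the read length on the
    right-pointing side).
    """
    med = model.median_is
    if strand == pointing_strand:
        lo = max(positions) + read_len
        hi = max(positions) + med
        center = mu + read_len
    else:
        # the junction may coincide exactly with the leftmost read start
        # (a fragment cut precisely at the junction), so the half-open
        # interval must reach one past it
        lo = min(positions) - med + read_len
        hi = min(positions) + 1
        center = mu
    if lo >= hi:
        half = 2.0 * model.sigma_is
        lo, hi = center - half, center + half
    lo = max(0, int(math.floor(lo)))
    hi = int(math.ceil(hi))
    if hi <= lo:
        hi = lo + 1
    return BreakpointInterval(chrom, lo, hi)


def breakpoint_intervals(
    cluster: DiscordantCluster, model: InsertSizeModel, read_len: int
) -> tuple[BreakpointInterval, BreakpointInterval]:
    """Derive the two breakpoint-containing intervals of a cluster.

    The alpha-side interval is built from the member first-read positions and
    the beta side from the second-read positions; the direction in which the
    junction lies relative to each read group follows from the side's strand
    and the library's expected orientation (see :func:`_side_interval`).
    Requires support >= 2.
    """
    if cluster.support < 2:
        raise ValueError("breakpoint intervals require a cluster of support >= 2")
    pointing = strands_of(model.expected_orientation)[0]
    left = _side_interval(
        cluster.chrom1, cluster.alphas, cluster.strand1, pointing,
        cluster.mu_alpha, model, read_len,
    )
    right = _side_interval(
        cluster.chrom2, cluster.betas, cluster.strand2, pointing,
        cluster.mu_beta, model, read_len,
    )
    return left, right


def write_bedpe(
    clusters: Iterable[DiscordantCluster],
    model: InsertSizeModel,
    read_len: int,
    path: str,
) -> None:
    """Export clusters as BEDPE (0-based half-open breakpoint intervals)."""
    with open(path, "w") as fh:
        for c in clusters:
            if c.support >= 2:
                left, right = breakpoint_intervals(c, model, read_len)
                l_lo, l_hi, r_lo, r_hi = left.lo, left.hi, right.lo, right.hi
            else:
                l_lo, l_hi = int(c.mu_alpha), int(c.mu_alpha) + 1
                r_lo, r_hi = int(c.mu_beta), int(c.mu_beta) + 1
            fh.write(
                f"{c.chrom1}\t{l_lo}\t{l_hi}\t{c.chrom2}\t{r_lo}\t{r_hi}\t"
                f"{c.cluster_id}\t{c.support}\t{c.strand1}\t{c.strand2}\n"
            )
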