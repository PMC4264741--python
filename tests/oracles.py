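"""Independent reference implementations used to cross-check the package.

These deliberately re-derive results by the most literal route available
(full candidate scans, per-base counting) and share no code with the
implementations they check.
"""

from __future__ import annotations

import math

import numpy as np

from svcall.alignments import InsertSizeModel, ReadPairRecord


def mk_pair(
    pair_id,
    alpha,
    beta,
    chrom1="chr1",
    chrom2=None,
    strand1="+",
    strand2="-",
    insert=None,
    read_len=50,
):
    """Terse ReadPairRecord builder for hand-written fixtures."""
    chrom2 = chrom2 or chrom1
    if insert is None and chrom1 == chrom2:
        insert = beta + read_len - alpha
    return ReadPairRecord(
        pair_id=str(pair_id),
        chrom1=chrom1,
        chrom2=chrom2,
        alpha=alpha,
        beta=beta,
        strand1=strand1,
        strand2=strand2,
        insert_size=insert if chrom1 == chrom2 else None,
    )


def brute_force_cluster(pairs, model: InsertSizeModel):
    """Literal clustering reference: no eviction, full scan of all clusters.

    Returns a list of clusters as dicts with keys ``members`` (pair ids in
    join order), ``mu_alpha``, ``mu_beta``.  Same member/closest/tie rules
    as the engine: 2 sigma windows on alpha, beta and (same-chromosome)
    insert, identical strand signature, join the Euclidean-closest
    candidate, earlier-created cluster wins ties.
    """
    sigma = model.sigma_is
    clusters = []
    for p in pairs:
        best = None
        best_d = math.inf
        for c in clusters:
            if (p.chrom1, p.chrom2) != c["key"][:2]:
                continue
            if (p.strand1, p.strand2) != c["key"][2:]:
                continue
            if abs(p.alpha - c["mu_alpha"]) > 2 * sigma:
                continue
            if abs(p.beta - c["mu_beta"]) > 2 * sigma:
                continue
            if c["mu_is"] is not None and p.insert_size is not None:
                if abs(p.insert_size - c["mu_is"]) > 2 * sigma:
                    continue
            d = math.hypot(p.alpha - c["mu_alpha"], p.beta - c["mu_beta"])
            if d < best_d:
                best, best_d = c, d
        if best is None:
            clusters.append(
                dict(
                    key=(p.chrom1, p.chrom2, p.strand1, p.strand2),
                    members=[p.pair_id],
                    alphas=[p.alpha],
                    betas=[p.beta],
                    mu_alpha=float(p.alpha),
                    mu_beta=float(p.beta),
                    mu_is=float(p.insert_size)
                    if p.chrom1 == p.chrom2 and p.insert_size is not None
                    else None,
                )
            )
        else:
            best["members"].append(p.pair_id)
            best["alphas"].append(p.alpha)
            best["betas"].append(p.beta)
            n = len(best["members"])
            best["mu_alpha"] += (p.alpha - best["mu_alpha"]) / n
            best["mu_beta"] += (p.beta - best["mu_beta"]) / n
            if best["mu_is"] is not None and p.insert_size is not None:
                best["mu_is"] += (p.insert_size - best["mu_is"]) / n
    return clusters


def random_cluster_instance(rng, n_max=200, span=100_000, sigma=300.0):
    """A random sorted discordant-pair instance plus its insert model."""
    n_groups = int(rng.integers(1, 8))
    pairs = []
    i = 0
    for _ in range(n_groups):
        ca = rng.integers(0, span)
        cb = rng.integers(0, span)
        base_insert = float(rng.integers(4000, 20_000))
        size = int(rng.integers(1, max(2, n_max // n_groups)))
        strands = ("+", "-") if rng.random() < 0.7 else ("-", "+")
        for _ in range(size):
            a = int(ca + rng.normal(0, sigma))
            b = int(cb + rng.normal(0, sigma))
            ins = int(base_insert + rng.normal(0, sigma / 2))
            pairs.append(
                mk_pair(f"p{i}", max(0, a), max(0, b), strand1=strands[0],
                        strand2=strands[1], insert=max(0, ins))
            )
            i += 1
    pairs.sort(key=lambda p: (p.chrom1, p.alpha))
    model = InsertSizeModel(
        median_is=3000.0, sigma_is=sigma, expected_orientation="FR",
        k_discordant=3.0, n_pairs_sampled=1000,
    )
    return pairs, model


def per_base_overlap_fraction(interval, track_intervals):
    """Per-base oracle for the covered fraction of ``interval``."""
    chrom, start, end = interval
    covered = np.zeros(end - start, dtype=bool)
    for c, s, e in track_intervals:
        if c != chrom:
            continue
        lo, hi = max(s, start), min(e, end)
        if hi > lo:
            covered[lo - start:hi - start] = True
    return covered.mean() if covered.size else 0.0


def naive_window_counts(positions, chrom_length, window, step):
    """Literal sliding-window counter (loop over windows and reads)."""
    starts = list(range(0, max(1, chrom_length), step))
    counts = []
    for s in starts:
        e = min(s + window, chrom_length)
        counts.append(sum(1 for p in positions if s <= p < e))
    return starts, counts


def partition_of(clusters):
    """Canonical partition (frozenset of frozensets of member ids)."""
    out = []
    for c in clusters:
        members = c["members"] if isinstance(c, dict) else c.member_ids
        out.append(frozenset(members))
    return frozenset(out)
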