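"""Depth-of-coverage (DOC) ratio analysis between a sample and a reference.

Mapped reads are counted in sliding windows along each chromosome; per
window a normalised log2 coverage ratio between sample and reference is
computed together with a two-sided probability under the no-change null.
Maximal runs of consecutive, same-sign, significant windows become CNV
segments (gain/loss).

The probability model is a Gaussian approximation to the log ratio of two
Poisson counts: on the log2 scale the null variance is
``(1/n_sample + 1/n_ref) / ln(2)^2``.  Windows with a zero count in either
sample get a continuity correction (0.5 added to each count) for the
corrected ratio and probability, and their uncorrected ``log2_ratio`` is
left undefined.  GC-content and mapability corrections are not applied; a
matched reference sample is assumed to absorb those confounders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "CoverageWindow",
    "CnvSegment",
    "choose_window_size",
    "window_starts",
    "count_in_windows",
    "ratio_and_probability",
    "make_windows",
    "call_segments",
    "write_bedgraph",
    "write_windows_tsv",
    "write_segments_bed",
]

_LN2 = math.log(2.0)


@dataclass(slots=True)
class CoverageWindow:
    """One genomic window with sample/reference counts and ratio statistics.

    ``log2_ratio`` is ``log2((n_s/N_s) / (n_r/N_r))`` and is ``None`` when
    either count is zero; ``log2_ratio_corr`` is always defined using the
    0.5 continuity correction when needed.  ``z`` and ``p_value`` come from
    the Gaussian-Poisson ratio model.
    """

    chrom: str
    start: int
    end: int
    count_sample: int
    count_ref: int
    log2_ratio: Optional[float] = None
    log2_ratio_corr: float = 0.0
    z: float = 0.0
    p_value: float = 1.0

    @property
    def flagged_zero(self) -> bool:
        return self.log2_ratio is None


@dataclass(slots=True)
class CnvSegment:
    """A run of consecutive significant windows with a consistent sign."""

    chrom: str
    start: int
    end: int
    mean_log2_ratio: float
    direction: str  # "gain" | "loss"
    n_windows: int
    window_span: int = 0  # typical single-window width, kept for CI reporting


def choose_window_size(
    total_mapped_reads_sample: int,
    total_mapped_reads_ref: int,
    genome_size: int,
    target_reads_per_window: int = 100,
) -> int:
    """Window size (bp) giving ~``target_reads_per_window`` reads per window
    in the shallower of the two samples; rounded up to the nearest 100 bp.
    """
    if min(total_mapped_reads_sample, total_mapped_reads_ref) <= 0:
        raise ValueError("cannot size windows with zero mapped reads")
    if genome_size <= 0 or target_reads_per_window <= 0:
        raise ValueError("genome size and read target must be positive")
    w = genome_size * target_reads_per_window / min(
        total_mapped_reads_sample, total_mapped_reads_ref
    )
    return max(100, int(math.ceil(w / 100.0)) * 100)


def window_starts(chrom_length: int, window: int, step: int) -> np.ndarray:
    """Start coordinates of sliding windows covering [0, chrom_length)."""
    if step <= 0 or window <= 0 or step > window:
        raise ValueError("require 0 < step <= window")
    last = max(0, chrom_length - 1)
    return np.arange(0, last + 1, step, dtype=np.int64)


def count_in_windows(
    positions: Sequence[int], chrom_length: int, window: int, step: int
) -> tuple[np.ndarray, np.ndarray]:
    """Count read anchor positions per sliding window on one chromosome.

    ``positions`` are the 5'-most mapped bases of the reads.  A read is
    counted in every window containing its anchor; with ``step == window``
    (non-overlapping windows) counts sum to the number of reads.  Returns
    ``(starts, counts)``.
    """
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    starts = window_starts(chrom_length, window, step)
    ends = np.minimum(starts + window, chrom_length)
    counts = np.searchsorted(pos, ends, side="left") - np.searchsorted(
        pos, starts, side="left"
    )
    return starts, counts.astype(np.int64)


def ratio_and_probability(
    w: CoverageWindow, total_sample: int, total_ref: int
) -> CoverageWindow:
    """Fill in the log2 ratio, z statistic and two-sided p-value of a window."""
    ns, nr = w.count_sample, w.count_ref
    scale = math.log2(total_ref / total_sample)  # normalisation offset
    if ns > 0 and nr > 0:
        w.log2_ratio = math.log2(ns / nr) + scale
        cs, cr = float(ns), float(nr)
    else:
        w.log2_ratio = None
        cs, cr = ns + 0.5, nr + 0.5
    w.log2_ratio_corr = math.log2(cs / cr) + scale
    sd = math.sqrt(1.0 / cs + 1.0 / cr) / _LN2
    w.z = w.log2_ratio_corr / sd
    w.p_value = float(2.0 * _scipy_stats.norm.sf(abs(w.z)))
    return w


def make_windows(
    sample_positions: dict[str, Sequence[int]],
    ref_positions: dict[str, Sequence[int]],
    chrom_lengths: dict[str, int],
    window: int,
    step: Optional[int] = None,
) -> list[CoverageWindow]:
    """Count both samples into shared windows and annotate ratio statistics.

    ``sample_positions``/``ref_positions`` map chromosome -> read anchor
    positions.  Default step is ``window // 2`` (half-overlapping windows).
    """
    if step is None:
        step = max(1, window // 2)
    total_s = sum(len(v) for v in sample_positions.values())
    total_r = sum(len(v) for v in ref_positions.values())
    if total_s == 0 or total_r == 0:
        raise ValueError("cannot compute coverage ratios with zero mapped reads")
    out: list[CoverageWindow] = []
    for chrom, length in chrom_lengths.items():
        starts, cs = count_in_windows(
            sample_positions.get(chrom, ()), length, window, step
        )
        _, cr = count_in_windows(ref_positions.get(chrom, ()), length, window, step)
        for s, a, b in zip(starts.tolist(), cs.tolist(), cr.tolist()):
            w = CoverageWindow(
                chrom=chrom,
                start=int(s),
                end=int(min(s + window, length)),
                count_sample=int(a),
                count_ref=int(b),
            )
            ratio_and_probability(w, total_s, total_r)
            out.append(w)
    return out


def call_segments(
    windows: Iterable[CoverageWindow],
    z_threshold: float = 3.0,
    min_consecutive: int = 3,
) -> list[CnvSegment]:
    """Rule-based CNV segmentation over annotated windows.

    Maximal runs of >= ``min_consecutive`` consecutive windows (per
    chromosome, in positional order) whose |z| exceeds ``z_threshold`` with
    a consistent ratio sign become segments spanning the first window start
    to the last window end.
    """
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    segs: list[CnvSegment] = []
    run: list[CoverageWindow] = []
    run_sign = 0
    run_chrom: Optional[str] = None

    def _flush():
        nonlocal run
        if len(run) >= min_consecutive:
            mean_lr = float(np.mean([w.log2_ratio_corr for w in run]))
            segs.append(
                CnvSegment(
                    chrom=run[0].chrom,
                    start=run[0].start,
                    end=run[-1].end,
                    mean_log2_ratio=mean_lr,
                    direction="gain" if mean_lr > 0 else "loss",
                    n_windows=len(run),
                    window_span=run[0].end - run[0].start,
                )
            )
        run = []

    for w in windows:
        sign = 0
        if abs(w.z) > z_threshold:
            sign = 1 if w.log2_ratio_corr > 0 else -1
        if sign != 0 and w.chrom == run_chrom and sign == run_sign:
            run.append(w)
        else:
            _flush()
            if sign != 0:
                run = [w]
                run_chrom, run_sign = w.chrom, sign
            else:
                run_chrom, run_sign = w.chrom, 0
    _flush()
    return segs


def write_bedgraph(windows: Iterable[CoverageWindow], path: str) -> None:
    """Write per-window corrected log2 ratios as bedGraph."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="log2_coverage_ratio"\n')
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.log2_ratio_corr:.4f}\n")


def write_windows_tsv(windows: Iterable[CoverageWindow], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# GC-content and mapability are not corrected; use a matched reference\n"
            "chrom\tstart\tend\tcount_sample\tcount_ref\tlog2_ratio\tp_value\n"
        )
        for w in windows:
            lr = "NA" if w.log2_ratio is None else f"{w.log2_ratio:.4f}"
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.count_sample}\t{w.count_ref}\t"
                f"{lr}\t{w.p_value:.3e}\n"
            )


def write_segments_bed(segments: Iterable[CnvSegment], path: str) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.direction}\t"
                f"{s.mean_log2_ratio:.4f}\t{s.n_windows}\n"
            )
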