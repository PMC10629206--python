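"""Windowed coverage log-ratio copy-number tracks and targeted gene calls.

WGS mode tiles the genome into fixed-width windows (1 kb by default),
computes per-window log2 coverage ratios of the tumor against a reference
sample after library-size normalization, and median-decimates the track to
suppress noise.  Targeted mode normalizes per-gene depths to CNA-free
baseline regions and calls only homozygous deletions and amplifications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import ReferenceGenome

SEGMENT_STATES = ("homozygous_deletion", "loss", "neutral", "gain", "amplification")


@dataclass
class CoverageTrack:
    """Fragment counts over consecutive 0-based half-open windows."""

    window_size: int
    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        self.counts = {
            c: np.asarray(v, dtype=float) for c, v in self.counts.items()
        }
        for c, v in self.counts.items():
            if (v < 0).any():
                raise ValueError(f"negative counts on {c}")

    def total(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))


@dataclass
class LogRatioTrack:
    """Per-window log2 ratios; NaN marks masked windows, -inf zero tumor
    coverage over nonzero reference."""

    window_size: int
    values: dict[str, np.ndarray]
    decimation_factor: int = 1


@dataclass
class SegmentThresholds:
    """Log2-ratio bands for automatic segment state assignment.

    The source pipeline read copy-number states off IGV tracks by eye;
    these bands replace the eye for testing and are deliberately config.
    """

    homozygous_deletion: float = -3.0  # ratio <= this
    loss: float = -0.4  # ratio <= this (and > homozygous_deletion)
    gain: float = 0.32  # ratio >= this (log2(5/4), one extra copy at 50% purity)
    amplification: float = 2.0  # ratio >= this


@dataclass(frozen=True)
class GeneCopyCall:
    gene: str
    state: str  # homozygous_deletion | amplification | not_called
    log_ratio: float


def count_windows(
    fragment_starts: dict[str, np.ndarray],
    genome: ReferenceGenome,
    window_size: int = 1000,
) -> CoverageTrack:
    """Histogram fragment start positions into fixed windows.

    Every fragment lands in exactly one window (by its start coordinate),
    so the total count is conserved.  Unsorted input is accepted.
    """
    lengths = genome.lengths
    counts = {}
    for chrom, length in lengths.items():
        n_windows = math.ceil(length / window_size)
        starts = np.asarray(fragment_starts.get(chrom, ()), dtype=np.int64)
        if starts.size and (starts.min() < 0 or starts.max() >= length):
            raise ValueError(f"fragment start out of bounds on {chrom}")
        counts[chrom] = np.bincount(
            starts // window_size, minlength=n_windows
        ).astype(float)
    return CoverageTrack(window_size=window_size, counts=counts)


def coverage_log_ratio(tumor: CoverageTrack, reference: CoverageTrack) -> LogRatioTrack:
    """log2((tumor_i / T) / (reference_i / R)) per window.

    T and R are the library-size totals, so a genome-wide depth difference
    cancels.  Windows with zero reference coverage are masked (NaN); zero
    tumor coverage over covered reference yields -inf.
    """
    if tumor.window_size != reference.window_size or set(tumor.counts) != set(
        reference.counts
    ):
        raise ValueError("tumor and reference tracks are on different grids")
    t_total, r_total = tumor.total(), reference.total()
    if t_total == 0 or r_total == 0:
        raise ValueError("empty coverage track")
    values = {}
    for chrom, t in tumor.counts.items():
        r = reference.counts[chrom]
        if t.shape != r.shape:
            raise ValueError(f"window grids differ on {chrom}")
        out = np.full(t.shape, np.nan)
        ok = r > 0
        with np.errstate(divide="ignore"):
            out[ok] = np.log2(t[ok] / t_total) - np.log2(r[ok] / r_total)
        values[chrom] = out
    return LogRatioTrack(window_size=tumor.window_size, values=values)


def _block_median(block: np.ndarray) -> float:
    block = block[~np.isnan(block)]
    if block.size == 0:
        return float("nan")
    return float(np.median(block))


def median_decimate(track: LogRatioTrack, factor: int = 200) -> LogRatioTrack:
    """Reduce consecutive blocks of ``factor`` windows to their median.

    Masked (NaN) members are ignored within a block; a trailing partial
    block uses whatever windows it has.  Output length is ceil(n/factor).
    """
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if factor == 1:
        return LogRatioTrack(
            window_size=track.window_size,
            values={c: v.copy() for c, v in track.values.items()},
            decimation_factor=track.decimation_factor,
        )
    values = {}
    for chrom, v in track.values.items():
        n_out = math.ceil(v.size / factor)
        values[chrom] = np.array(
            [_block_median(v[i * factor : (i + 1) * factor]) for i in range(n_out)]
        )
    return LogRatioTrack(
        window_size=track.window_size,
        values=values,
        decimation_factor=track.decimation_factor * factor,
    )


def _state_of(value: float, thr: SegmentThresholds) -> str:
    if np.isnan(value):
        return "masked"
    if value <= thr.homozygous_deletion:
        return "homozygous_deletion"
    if value <= thr.loss:
        return "loss"
    if value >= thr.amplification:
        return "amplification"
    if value >= thr.gain:
        return "gain"
    return "neutral"


def call_segments(
    track: LogRatioTrack, thresholds: SegmentThresholds | None = None
) -> list[tuple[str, int, int, str]]:
    """Maximal runs of windows sharing a threshold band.

    Returns ``(chrom, start_bp, end_bp, state)`` tuples in genomic order;
    coordinates are in base pairs on the decimated grid.  Masked windows
    are skipped (they terminate runs but produce no segment).
    """
    thr = thresholds or SegmentThresholds()
    step = track.window_size * track.decimation_factor
    segments = []
    for chrom, v in track.values.items():
        run_state, run_start = None, 0
        for i, value in enumerate(v):
            state = _state_of(float(value), thr)
            if state != run_state:
                if run_state is not None and run_state != "masked":
                    segments.append((chrom, run_start * step, i * step, run_state))
                run_state, run_start = state, i
        if run_state is not None and run_state != "masked":
            segments.append((chrom, run_start * step, v.size * step, run_state))
    return segments


def targeted_gene_copy_state(
    gene_depths: dict[str, float],
    baseline_depths,
    deletion_threshold: float = -2.5,
    amplification_threshold: float = 2.0,
    pseudo: float = 0.01,
) -> list[GeneCopyCall]:
    """Per-gene log2 ratio against the median of CNA-free baseline regions.

    Only homozygous deletions and amplifications are called; intermediate
    (hemizygous) states map to ``not_called``.
    """
    baseline = np.asarray(list(baseline_depths), dtype=float)
    if baseline.size == 0:
        raise ValueError("baseline regions required")
    base = float(np.median(baseline))
    if base <= 0:
        raise ValueError("zero baseline depth")
    calls = []
    for gene, depth in gene_depths.items():
        ratio = math.log2((depth + pseudo) / base)
        if ratio <= deletion_threshold:
            state = "homozygous_deletion"
        elif ratio >= amplification_threshold:
            state = "amplification"
        else:
            state = "not_called"
        calls.append(GeneCopyCall(gene=gene, state=state, log_ratio=ratio))
    return calls
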