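"""Windowed read-depth computation and GC normalization.

Coverage is summarised in non-overlapping fixed-size windows (default 300 bp)
tiling each chromosome; a read contributes to exactly one window, the one
containing its alignment start.  Raw counts are placed on a copy-number scale
by dividing each window's count by the mean count over all autosomal,
accessible windows with the same integer GC percentage, then multiplying by
two so that diploid regions have expected normalized coverage 2.

Windows where depth is an unreliable proxy for copy number are masked out:
windows with an excess of mapping-quality-zero reads, and windows whose GC
percentage is so rare among accessible autosomal windows that the
normalizing constant cannot be estimated reliably.  Windows surviving both
rules are the "kept" (filtered) windows, and all downstream copy-number
inference happens in kept-window coordinate space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "WindowGrid",
    "CoverageMatrix",
    "WindowFilter",
    "MQ0_EXCESS",
    "GC_RARE",
    "count_reads_in_windows",
    "compute_gc_normalizing_constants",
    "normalize_coverage",
    "build_window_filter",
]

# reason codes for dropped windows
MQ0_EXCESS = "MQ0_EXCESS"
GC_RARE = "GC_RARE"

#: required columns of a window-track table
TRACK_COLUMNS = ("chrom", "start", "end", "gc", "accessibility", "mq0_frac")


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping fixed-size windows on one chromosome.

    Windows are half-open, 0-based: window ``i`` spans
    ``[i * window_size, (i + 1) * window_size)``.  A trailing partial window
    is not part of the grid.
    """

    chrom: str
    length: int
    window_size: int = 300

    def __post_init__(self) -> None:
        if self.length < self.window_size:
            raise ValueError(
                f"chromosome {self.chrom!r} shorter than one window "
                f"({self.length} < {self.window_size})"
            )

    @property
    def n_windows(self) -> int:
        return self.length // self.window_size

    def window_of(self, pos: int) -> int:
        """Window index containing 0-based position ``pos``."""
        if pos < 0 or pos >= self.length:
            raise ValueError(f"position {pos} outside {self.chrom} (length {self.length})")
        return pos // self.window_size

    def window_bounds(self, index: int) -> tuple[int, int]:
        """Genomic ``(start, end)`` of window ``index`` (half-open)."""
        if not 0 <= index < self.n_windows:
            raise IndexError(index)
        return index * self.window_size, (index + 1) * self.window_size


@dataclass
class CoverageMatrix:
    """Per-sample windowed counts plus window annotation tracks.

    ``tracks`` has one row per window (all chromosomes concatenated) with
    columns chrom/start/end/gc/accessibility/mq0_frac; ``counts`` is a
    ``(n_samples, n_windows)`` integer array aligned to it.  ``norm`` holds
    normalized coverage on the copy-number scale once computed (NaN where no
    normalizing constant exists).
    """

    samples: list[str]
    tracks: pd.DataFrame
    counts: np.ndarray
    norm: np.ndarray | None = None
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), len(self.tracks)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.tracks)} windows"
            )
        if (self.counts < 0).any():
            raise ValueError("raw counts must be non-negative")
        missing = set(TRACK_COLUMNS) - set(self.tracks.columns)
        if missing:
            raise ValueError(f"tracks missing columns: {sorted(missing)}")

    @property
    def n_windows(self) -> int:
        return len(self.tracks)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def autosomal_mask(self, sex_chroms: tuple[str, ...] = ("X",)) -> np.ndarray:
        return ~self.tracks["chrom"].isin(sex_chroms).to_numpy()

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return (self.tracks["chrom"] == chrom).to_numpy()


@dataclass
class WindowFilter:
    """Boolean keep-flag per window with reason codes for dropped windows."""

    keep: np.ndarray
    reasons: dict[int, list[str]] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def kept_indices(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Global indices of kept windows, optionally restricted to ``mask``."""
        m = self.keep if mask is None else (self.keep & mask)
        return np.flatnonzero(m)


def _is_countable(read: pysam.AlignedSegment, include_duplicates: bool,
                  include_secondary: bool) -> bool:
    if read.is_unmapped:
        return False
    if not include_secondary and (read.is_secondary or read.is_supplementary):
        return False
    if not include_duplicates and read.is_duplicate:
        return False
    return True


def count_reads_in_windows(
    alignments: str | pysam.AlignmentFile,
    grid: WindowGrid,
    *,
    include_duplicates: bool = False,
    include_secondary: bool = False,
) -> np.ndarray:
    """Count aligned reads per window of ``grid``.

    Each mapped read is counted once, in the window containing its alignment
    start (reference_start, 0-based).  Reads starting in the trailing partial
    window (if any) are ignored.  Duplicates and secondary/supplementary
    alignments are excluded by default.

    Parameters
    ----------
    alignments : path to a SAM/BAM file, or an open pysam.AlignmentFile.
    grid : window grid for the chromosome to count.

    Returns
    -------
    Integer array of length ``grid.n_windows``.
    """
    close = False
    if isinstance(alignments, str):
        alignments = pysam.AlignmentFile(alignments)
        close = True
    try:
        counts = np.zeros(grid.n_windows, dtype=np.int64)
        for read in alignments.fetch(grid.chrom) if alignments.has_index() \
                else alignments:
            if not _is_countable(read, include_duplicates, include_secondary):
                continue
            if read.reference_name != grid.chrom:
                continue
            start = read.reference_start
            if start >= grid.length:
                raise ValueError(
                    f"alignment start {start} beyond {grid.chrom} length {grid.length}"
                )
            w = start // grid.window_size
            if w < grid.n_windows:  # trailing partial window dropped
                counts[w] += 1
        return counts
    finally:
        if close:
            alignments.close()


def compute_gc_normalizing_constants(
    counts: np.ndarray,
    tracks: pd.DataFrame,
    *,
    sex_chroms: tuple[str, ...] = ("X",),
    min_accessibility: float = 0.90,
) -> np.ndarray:
    """Per-sample mean raw count for each GC percentage bin.

    The constant for GC bin ``g`` is the mean raw count over autosomal
    windows with ``gc == g`` and accessibility >= ``min_accessibility``.
    Restricting to well-accessible autosomal windows keeps copy-variable and
    ambiguously-mapped regions from contaminating the expectation.

    Returns
    -------
    Array of shape ``(n_samples, 101)`` indexed by GC percent 0..100; NaN for
    GC bins with no eligible window.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    gc = tracks["gc"].to_numpy()
    eligible = (
        ~tracks["chrom"].isin(sex_chroms).to_numpy()
        & (tracks["accessibility"].to_numpy() >= min_accessibility)
    )
    constants = np.full((counts.shape[0], 101), np.nan)
    for g in np.unique(gc[eligible]):
        sel = eligible & (gc == g)
        constants[:, int(g)] = counts[:, sel].mean(axis=1)
    return constants


def normalize_coverage(counts: np.ndarray, constants: np.ndarray,
                       tracks: pd.DataFrame) -> np.ndarray:
    """Scale raw counts to normalized coverage (diploid baseline 2).

    ``normalized = 2 * count / constant[gc(window)]`` per sample.  Windows
    whose GC bin has no constant, or a zero constant, get NaN.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    constants = np.atleast_2d(constants)
    gc = tracks["gc"].to_numpy().astype(int)
    denom = constants[:, gc]  # (n_samples, n_windows)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = 2.0 * counts / denom
    norm[~np.isfinite(norm)] = np.nan
    return norm


def build_window_filter(
    tracks: pd.DataFrame,
    *,
    sex_chroms: tuple[str, ...] = ("X",),
    max_mq0_frac: float = 0.02,
    min_gc_bin_windows: int = 100,
    min_accessibility: float = 0.90,
) -> WindowFilter:
    """Build the analysis window mask from annotation tracks alone.

    A window is dropped iff its pooled MQ0 read fraction exceeds
    ``max_mq0_frac`` (strict inequality: exactly 2% is kept), or its GC
    percentage is represented by fewer than ``min_gc_bin_windows`` accessible
    autosomal windows, which makes the GC normalizing constant unreliable.
    """
    gc = tracks["gc"].to_numpy().astype(int)
    mq0 = tracks["mq0_frac"].to_numpy()
    accessible_auto = (
        ~tracks["chrom"].isin(sex_chroms).to_numpy()
        & (tracks["accessibility"].to_numpy() >= min_accessibility)
    )
    bin_support = np.bincount(gc[accessible_auto], minlength=101)

    mq0_bad = mq0 > max_mq0_frac
    gc_bad = bin_support[gc] < min_gc_bin_windows
    keep = ~(mq0_bad | gc_bad)

    reasons: dict[int, list[str]] = {}
    for i in np.flatnonzero(~keep):
        r = []
        if mq0_bad[i]:
            r.append(MQ0_EXCESS)
        if gc_bad[i]:
            r.append(GC_RARE)
        reasons[int(i)] = r
    return WindowFilter(keep=keep, reasons=reasons)
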