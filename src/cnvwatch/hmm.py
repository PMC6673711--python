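"""Gaussian-HMM copy-number state inference and raw CNV calling.

Each sample's normalized coverage (diploid baseline 2) is decoded with a
hidden Markov model whose states are integer copy numbers 0..K.  Emissions
are Gaussian with mean equal to the state and a variance affine in the
state (read-depth noise grows with copy number); the per-sample variance
scale is estimated robustly (MAD) from autosomal kept windows so that CNVs
do not inflate it.  Transitions between distinct states share a single
small probability, making state changes rare a priori.

Amplification calls are maximal runs of at least ``min_windows`` kept
windows whose decoded state exceeds the baseline copy number (2 on
autosomes and the female X, 1 on the male X).  Contiguity is measured in
kept-window index space: windows removed by the coverage filter do not
break a run.  Each raw call is then screened by the likelihood ratio of
the decoded states against a constant-baseline null; calls with ratio
below 1000 are discarded.

``shuffle_fdr_simulation`` and ``sensitivity_simulation`` estimate the
false-call rate of this procedure on coverage with genome-wide shuffled
windows, and its power to recover planted amplifications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix, WindowFilter

__all__ = [
    "HMMParams",
    "RawCNVCall",
    "viterbi_cns",
    "extract_raw_cnvs",
    "likelihood_ratio_filter",
    "call_sample",
    "call_cohort",
    "shuffle_fdr_simulation",
    "sensitivity_simulation",
]

LOG_LR_THRESHOLD = math.log(1000.0)


@dataclass(frozen=True)
class HMMParams:
    """Copy-number HMM parameters.

    States are 0..``max_state`` with Gaussian emissions of mean ``k`` and
    variance ``var_base + k * var_slope``; ``transition`` is the probability
    of moving to each particular different state (self-transition
    ``1 - max_state * transition``).
    """

    max_state: int = 12
    transition: float = 1e-5
    var_base: float = 0.065
    var_slope: float = 0.0325

    def __post_init__(self) -> None:
        if self.max_state < 1:
            raise ValueError("max_state must be >= 1")
        if not 0 < self.transition < 1.0 / self.max_state:
            raise ValueError("transition probability out of range")
        if self.var_base <= 0 or self.var_slope < 0:
            raise ValueError("variances must be positive")

    @property
    def n_states(self) -> int:
        return self.max_state + 1

    @property
    def means(self) -> np.ndarray:
        return np.arange(self.n_states, dtype=float)

    @property
    def variances(self) -> np.ndarray:
        return self.var_base + self.means * self.var_slope

    @classmethod
    def from_coverage(cls, values: np.ndarray, *, max_state: int = 12,
                      transition: float = 1e-5) -> "HMMParams":
        """Estimate the variance scale from a sample's diploid coverage.

        ``values`` should be autosomal kept-window normalized coverage.  The
        variance at the diploid state (k=2) is set to the squared
        MAD-estimated scale, which resists contamination by CNV windows;
        the affine profile fixes var(0) at half that and grows linearly.
        """
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            raise ValueError("no finite coverage values to estimate variance from")
        mad = np.median(np.abs(values - np.median(values)))
        sigma2 = max((1.4826 * mad) ** 2, 1e-4)
        return cls(max_state=max_state, transition=transition,
                   var_base=sigma2 / 2.0, var_slope=sigma2 / 4.0)


@dataclass
class RawCNVCall:
    """A per-sample amplification call: a run of amplified-state windows."""

    sample_id: str
    chrom: str
    start_window: int  # chromosome-local index of first window
    end_window: int    # chromosome-local index of last window (inclusive)
    start: int         # genomic bp, 0-based half-open
    end: int
    n_windows: int     # kept windows spanned
    cns: int           # modal decoded state over the run
    baseline: int
    log_likelihood_ratio: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _log_emissions(values: np.ndarray, params: HMMParams) -> np.ndarray:
    x = values[:, None] - params.means[None, :]
    var = params.variances[None, :]
    return -0.5 * (np.log(2 * np.pi * var) + x * x / var)


def viterbi_cns(values: np.ndarray, params: HMMParams | None = None) -> np.ndarray:
    """Most likely copy-number state path for one sample on one chromosome.

    ``values`` is normalized coverage on kept windows (ordered).  The state
    prior is uniform.  Ties are broken toward the lower copy number.
    Returns an integer state array of the same length; empty input yields
    an empty path.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.zeros(0, dtype=int)
    if not np.isfinite(values).all():
        raise ValueError("coverage values must be finite on kept windows")
    if params is None:
        params = HMMParams.from_coverage(values)

    S = params.n_states
    log_self = math.log(1.0 - params.max_state * params.transition)
    log_switch = math.log(params.transition)
    logT = np.full((S, S), log_switch)
    np.fill_diagonal(logT, log_self)

    emit = _log_emissions(values, params)
    n = len(values)
    back = np.zeros((n, S), dtype=np.int32)
    alpha = emit[0] - math.log(S)  # uniform prior
    for t in range(1, n):
        scores = alpha[:, None] + logT
        best = np.argmax(scores, axis=0)  # first max -> lower previous state
        back[t] = best
        alpha = scores[best, np.arange(S)] + emit[t]

    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(alpha))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def baseline_state(chrom: str, sex: str, sex_chroms: tuple[str, ...] = ("X",)) -> int:
    return 1 if (chrom in sex_chroms and sex == "M") else 2


def extract_raw_cnvs(
    path: np.ndarray,
    kept_windows: pd.DataFrame,
    sample_id: str,
    chrom: str,
    sex: str = "F",
    min_windows: int = 5,
) -> list[RawCNVCall]:
    """Extract maximal amplified runs of at least ``min_windows`` windows.

    ``kept_windows`` holds the chromosome's kept windows (columns start/end,
    same order as ``path``).  A window is amplified when its state exceeds
    the baseline (2, or 1 on the male X).  Runs are maximal in kept-window
    index space; genomic coordinates span from the start of the first to
    the end of the last window in the run.
    """
    path = np.asarray(path)
    if len(path) != len(kept_windows):
        raise ValueError("path length does not match kept windows")
    base = baseline_state(chrom, sex)
    amplified = path > base
    calls: list[RawCNVCall] = []
    starts = kept_windows["start"].to_numpy()
    ends = kept_windows["end"].to_numpy()
    window_size = int(ends[0] - starts[0]) if len(kept_windows) else 0

    i = 0
    n = len(path)
    while i < n:
        if not amplified[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and amplified[j + 1]:
            j += 1
        if j - i + 1 >= min_windows:
            run_states = path[i:j + 1]
            vals, counts = np.unique(run_states, return_counts=True)
            calls.append(RawCNVCall(
                sample_id=sample_id,
                chrom=chrom,
                start_window=int(starts[i]) // window_size,
                end_window=int(starts[j]) // window_size,
                start=int(starts[i]),
                end=int(ends[j]),
                n_windows=j - i + 1,
                cns=int(vals[np.argmax(counts)]),
                baseline=base,
            ))
        i = j + 1
    return calls


def _log_normal(x: np.ndarray, mean: float | np.ndarray, var: float | np.ndarray
                ) -> np.ndarray:
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def likelihood_ratio_filter(
    call: RawCNVCall,
    values: np.ndarray,
    path: np.ndarray,
    params: HMMParams,
    threshold: float = 1000.0,
) -> tuple[bool, float]:
    """Likelihood ratio of the decoded states against a constant baseline.

    ``values``/``path`` are the coverage and decoded states over exactly the
    call's windows.  The ratio compares per-window Gaussians at the decoded
    state versus a null of constant baseline copy number (2 on autosomes,
    1 on the male X).  Computed in log space; the call is kept iff
    ratio >= ``threshold`` (the boundary value is kept).

    Returns ``(keep, log_likelihood_ratio)`` and records the ratio on the
    call.
    """
    values = np.asarray(values, dtype=float)
    path = np.asarray(path)
    if values.shape != path.shape:
        raise ValueError("values and path must align")
    var = params.variances
    log_alt = _log_normal(values, path.astype(float), var[path])
    null = call.baseline
    log_null = _log_normal(values, float(null), var[null])
    log_lr = float(np.sum(log_alt) - np.sum(log_null))
    call.log_likelihood_ratio = log_lr
    # tolerance so that a ratio of exactly the threshold is kept despite
    # floating-point rounding
    return log_lr >= math.log(threshold) - 1e-9, log_lr


def call_sample(
    norm_row: np.ndarray,
    tracks: pd.DataFrame,
    window_filter: WindowFilter,
    sample_id: str,
    sex: str = "F",
    params: HMMParams | None = None,
    *,
    min_windows: int = 5,
    lr_threshold: float = 1000.0,
    sex_chroms: tuple[str, ...] = ("X",),
) -> list[RawCNVCall]:
    """Run the full per-sample calling chain over all chromosomes.

    Decodes each chromosome's kept-window coverage, extracts amplified runs
    and applies the likelihood-ratio filter.  HMM variances are estimated
    from the sample's autosomal kept windows unless ``params`` is given.
    """
    norm_row = np.asarray(norm_row, dtype=float)
    keep = window_filter.keep & np.isfinite(norm_row)
    if params is None:
        auto = keep & ~tracks["chrom"].isin(sex_chroms).to_numpy()
        params = HMMParams.from_coverage(norm_row[auto])
    calls: list[RawCNVCall] = []
    for chrom in tracks["chrom"].unique():
        mask = keep & (tracks["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        values = norm_row[idx]
        path = viterbi_cns(values, params)
        kept_windows = tracks.iloc[idx][["start", "end"]].reset_index(drop=True)
        raw = extract_raw_cnvs(path, kept_windows, sample_id, chrom, sex,
                               min_windows=min_windows)
        for call in raw:
            # locate the call's run inside the kept-window arrays
            i0 = int(np.flatnonzero(kept_windows["start"].to_numpy() == call.start)[0])
            i1 = int(np.flatnonzero(kept_windows["end"].to_numpy() == call.end)[0])
            keep_call, _ = likelihood_ratio_filter(
                call, values[i0:i1 + 1], path[i0:i1 + 1], params, lr_threshold)
            if keep_call:
                calls.append(call)
    return calls


def call_cohort(
    cov: CoverageMatrix,
    window_filter: WindowFilter,
    *,
    min_windows: int = 5,
    lr_threshold: float = 1000.0,
) -> list[RawCNVCall]:
    """Per-sample calling for every sample of a cohort coverage matrix."""
    if cov.norm is None:
        raise ValueError("CoverageMatrix.norm not computed")
    calls: list[RawCNVCall] = []
    for i, sample_id in enumerate(cov.samples):
        sex = cov.sex.get(sample_id, "F")
        calls.extend(call_sample(
            cov.norm[i], cov.tracks, window_filter, sample_id, sex,
            min_windows=min_windows, lr_threshold=lr_threshold,
        ))
    return calls


@dataclass
class FDRReport:
    reps: int
    calls_per_rep: list[int]
    n_samples: int

    @property
    def mean_calls_per_sample(self) -> float:
        return float(np.mean(self.calls_per_rep)) / self.n_samples


def shuffle_fdr_simulation(
    cov: CoverageMatrix,
    window_filter: WindowFilter,
    reps: int,
    seed: int,
    *,
    min_windows: int = 5,
    lr_threshold: float = 1000.0,
) -> FDRReport:
    """False-call rate on genome-wide shuffled coverage.

    For each repetition, every sample's kept-window normalized coverage is
    permuted within each chromosome (destroying any spatial structure while
    preserving the marginal distribution; permuting within chromosomes
    keeps diploid autosomal values off the haploid male X, whose baseline
    differs), the full per-sample calling chain is rerun, and the surviving
    calls are counted.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if cov.norm is None:
        raise ValueError("CoverageMatrix.norm not computed")
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(reps):
        n_calls = 0
        for i, sample_id in enumerate(cov.samples):
            row = cov.norm[i].copy()
            keep = window_filter.keep & np.isfinite(row)
            for chrom in cov.tracks["chrom"].unique():
                idx = np.flatnonzero(keep & cov.chrom_mask(chrom))
                row[idx] = rng.permutation(row[idx])
            calls = call_sample(row, cov.tracks, window_filter, sample_id,
                                cov.sex.get(sample_id, "F"),
                                min_windows=min_windows,
                                lr_threshold=lr_threshold)
            n_calls += len(calls)
        counts.append(n_calls)
    return FDRReport(reps=reps, calls_per_rep=counts, n_samples=len(cov.samples))


def sensitivity_simulation(
    depth: float,
    cnv_length_windows: int,
    copy_number: int,
    reps: int,
    seed: int,
    *,
    dispersion: float = 1.0,
    n_windows: int = 300,
    min_windows: int = 5,
    lr_threshold: float = 1000.0,
) -> float:
    """Fraction of planted amplifications recovered by per-sample calling.

    Each repetition simulates one diploid sample on a single autosome of
    ``n_windows`` 300-bp windows, plants one amplification of
    ``cnv_length_windows`` windows at total copy number ``copy_number`` in
    the middle, runs normalization and the calling chain, and scores the
    plant as recovered when some surviving call overlaps it.
    ``copy_number=2`` means no gain and always scores 0.
    """
    from . import simulate as sim
    from .coverage import (build_window_filter, compute_gc_normalizing_constants,
                           normalize_coverage)

    if cnv_length_windows < 1:
        raise ValueError("cnv_length_windows must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if copy_number <= 2:
        return 0.0

    rng = np.random.default_rng(seed)
    ref = sim.make_reference(
        int(rng.integers(2**31)),
        chrom_spec=(("2R", n_windows * 300),),
        het_fraction=0.0, gene_density=0.0,
        low_access_fraction=0.0, mq0_high_fraction=0.0,
    )
    wf = build_window_filter(ref.tracks, min_gc_bin_windows=1)
    start_w = n_windows // 2 - cnv_length_windows // 2
    sample = sim.SimulatedSample("s0", mean_depth=depth, dispersion=dispersion)
    cnv = sim.PlantedCNV("s0", "2R", start_w, start_w + cnv_length_windows - 1,
                         copies_added_per_chromosome=copy_number - 2, zygosity=1)
    recovered = 0
    for _ in range(reps):
        cov = sim.simulate_window_counts(ref, [sample], [cnv],
                                         int(rng.integers(2**31)))
        constants = compute_gc_normalizing_constants(cov.counts, cov.tracks)
        norm = normalize_coverage(cov.counts, constants, cov.tracks)
        calls = call_sample(norm[0], cov.tracks, wf, "s0", "F",
                            min_windows=min_windows, lr_threshold=lr_threshold)
        lo, hi = start_w * 300, (start_w + cnv_length_windows) * 300
        if any(c.start < hi and c.end > lo for c in calls):
            recovered += 1
    return recovered / reps
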