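"""End-to-end CNV discovery: coverage matrix in, cohort variants out.

Chains the standard stages: GC normalization, window filtering, sample
variance QC, per-sample HMM calling with the likelihood-ratio filter,
cross-sample matching, and the population frequency filter.  Each stage is
also available individually from its own module; this wrapper fixes the
plumbing for the common case.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import cohort as ch
from . import coverage as cov
from . import hmm
from .cohort import CNVVariant, SampleQCReport
from .coverage import CoverageMatrix, WindowFilter
from .hmm import RawCNVCall

__all__ = ["PipelineResult", "discover_cnvs"]


@dataclass
class PipelineResult:
    window_filter: WindowFilter
    qc: list[SampleQCReport]
    raw_calls: list[RawCNVCall]
    variants: list[CNVVariant]          # after matching
    retained: list[CNVVariant]          # after the frequency filter


def discover_cnvs(
    cm: CoverageMatrix,
    manifest: pd.DataFrame,
    *,
    min_gc_bin_windows: int = 100,
    variance_threshold: float = 0.2,
    min_windows: int = 5,
    lr_threshold: float = 1000.0,
) -> PipelineResult:
    """Run the full discovery chain on a raw-counts coverage matrix.

    ``manifest`` needs sample_id / population columns (sex is taken from
    the coverage matrix).  Samples failing the coverage-variance QC are
    excluded from calling and from population sizes.
    """
    constants = cov.compute_gc_normalizing_constants(cm.counts, cm.tracks)
    cm.norm = cov.normalize_coverage(cm.counts, constants, cm.tracks)
    wf = cov.build_window_filter(cm.tracks, min_gc_bin_windows=min_gc_bin_windows)

    qc = ch.filter_samples_by_variance(cm, wf, threshold=variance_threshold)
    passed = {r.sample_id for r in qc if r.passed}

    raw_calls: list[RawCNVCall] = []
    for i, sample_id in enumerate(cm.samples):
        if sample_id not in passed:
            continue
        raw_calls.extend(hmm.call_sample(
            cm.norm[i], cm.tracks, wf, sample_id, cm.sex.get(sample_id, "F"),
            min_windows=min_windows, lr_threshold=lr_threshold,
        ))

    variants = ch.match_cnvs(raw_calls)
    man = manifest[manifest["sample_id"].isin(passed)]
    retained = ch.population_frequency_filter(variants, man)
    return PipelineResult(window_filter=wf, qc=qc, raw_calls=raw_calls,
                          variants=variants, retained=retained)
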