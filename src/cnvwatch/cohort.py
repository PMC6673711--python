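"""Cohort-level CNV processing: sample QC, call matching, frequency filter.

Samples with erratic coverage (variance of normalized coverage above 0.2
over autosomal kept windows) are removed before any cohort analysis.  Raw
per-sample calls are then grouped into variants: two calls describe the
same CNV when both predicted breakpoints agree to within one window.
Grouping is greedy and anchor-based — the first call (in sorted order)
seeds a variant and later calls join the earliest anchor they match —
because the pairwise "same CNV" relation is not transitive.  Finally,
variants seen in too few carriers anywhere are dropped: a variant is kept
if some population has carrier frequency >= 5% (populations of at least 40
QC-passed samples) or at least three carriers (smaller populations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix, WindowFilter
from .hmm import RawCNVCall

__all__ = [
    "SampleQCReport",
    "CNVVariant",
    "filter_samples_by_variance",
    "match_cnvs",
    "population_frequency_filter",
]


@dataclass
class SampleQCReport:
    sample_id: str
    variance: float
    passed: bool


@dataclass
class CNVVariant:
    """A cohort-level CNV: matched per-sample calls with consensus coordinates."""

    variant_id: str
    chrom: str
    start: int  # consensus: median of member-call starts (bp)
    end: int
    members: list[RawCNVCall] = field(default_factory=list)

    @property
    def carriers(self) -> list[str]:
        return sorted({c.sample_id for c in self.members})

    @property
    def n_carriers(self) -> int:
        return len({c.sample_id for c in self.members})

    @property
    def length(self) -> int:
        return self.end - self.start


def filter_samples_by_variance(
    cov: CoverageMatrix,
    window_filter: WindowFilter,
    threshold: float = 0.2,
    *,
    sex_chroms: tuple[str, ...] = ("X",),
) -> list[SampleQCReport]:
    """Flag samples whose autosomal normalized-coverage variance exceeds 0.2.

    The rule is strict: a variance of exactly the threshold passes.
    """
    if cov.norm is None:
        raise ValueError("CoverageMatrix.norm not computed")
    mask = window_filter.keep & cov.autosomal_mask(sex_chroms)
    if not mask.any():
        raise ValueError("no autosomal kept windows")
    reports = []
    for i, sample_id in enumerate(cov.samples):
        vals = cov.norm[i, mask]
        vals = vals[np.isfinite(vals)]
        var = float(np.var(vals))
        reports.append(SampleQCReport(sample_id, var, var <= threshold))
    return reports


def match_cnvs(calls: list[RawCNVCall]) -> list[CNVVariant]:
    """Group per-sample calls into cohort variants by breakpoint proximity.

    A call joins an existing variant iff both its start and end window
    indices are within one window of the variant's *anchor* call (the call
    that seeded the variant); otherwise it seeds a new variant.  Calls are
    processed sorted by (chrom, start, end, sample), and a call matching
    several anchors joins the earliest, so the grouping is deterministic and
    partitions the input.  Consensus coordinates are the medians of member
    start/end positions.
    """
    ordered = sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.sample_id))
    anchors: list[RawCNVCall] = []
    groups: list[list[RawCNVCall]] = []
    for call in ordered:
        for anchor, group in zip(anchors, groups):
            if (anchor.chrom == call.chrom
                    and abs(call.start_window - anchor.start_window) <= 1
                    and abs(call.end_window - anchor.end_window) <= 1):
                group.append(call)
                break
        else:
            anchors.append(call)
            groups.append([call])

    variants = []
    for k, group in enumerate(groups):
        start = int(np.median([c.start for c in group]))
        end = int(np.median([c.end for c in group]))
        variants.append(CNVVariant(
            variant_id=f"cnv{k:05d}",
            chrom=group[0].chrom,
            start=start,
            end=end,
            members=group,
        ))
    return variants


def population_frequency_filter(
    variants: list[CNVVariant],
    manifest: pd.DataFrame,
    *,
    min_frequency: float = 0.05,
    small_population: int = 40,
    min_carriers_small: int = 3,
) -> list[CNVVariant]:
    """Drop variants not reaching the per-population carrier threshold.

    ``manifest`` must have columns sample_id and population, listing the
    QC-passed samples only (population sizes are evaluated on it).  A
    variant is kept iff some population has carriers/size >= 5% (size >= 40)
    or >= 3 carriers (size < 40).
    """
    pop_of = dict(zip(manifest["sample_id"], manifest["population"]))
    pop_sizes = manifest["population"].value_counts().to_dict()
    kept = []
    for v in variants:
        counts: dict[str, int] = {}
        for s in v.carriers:
            if s not in pop_of:
                raise ValueError(f"carrier {s!r} missing from manifest")
            counts[pop_of[s]] = counts.get(pop_of[s], 0) + 1
        for pop, n in counts.items():
            size = pop_sizes[pop]
            if size >= small_population:
                if n / size >= min_frequency:
                    kept.append(v)
                    break
            elif n >= min_carriers_small:
                kept.append(v)
                break
    return kept
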