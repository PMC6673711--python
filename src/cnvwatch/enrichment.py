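"""Permutation-based enrichment tests for CNV placement and gene content.

Observed counts — CNVs overlapping heterochromatin, CNVs containing at
least one gene, gene-containing CNVs holding a metabolic detox gene — are
compared to Monte-Carlo nulls that preserve the structure of the observed
call set.  The position null re-places each variant uniformly among all
start positions on its chromosome where its kept-window footprint fits
(optionally restricted to euchromatin); the gene-identity null keeps each
genic variant's number of consecutive genes fixed but reassigns which run
of consecutive genes it covers.  Two-tailed p-values are twice the
fraction of simulations producing at least as extreme a count as observed,
capped at 1; when no simulation reaches the observed count the p-value is
an upper bound of 2/n_sims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CNVVariant
from .coverage import WindowFilter

__all__ = [
    "EnrichmentResult",
    "classify_chromatin",
    "simulate_position_null",
    "PositionNullResult",
    "gene_kept_ranges",
    "genes_copied",
    "simulate_gene_identity_null",
    "compare_sizes",
    "SizeComparison",
    "fisher_contingency",
]

Interval = tuple[int, int]


@dataclass
class EnrichmentResult:
    """Observed statistic against a Monte-Carlo null distribution."""

    observed: int
    null: np.ndarray

    @property
    def n_sims(self) -> int:
        return len(self.null)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null))

    @property
    def null_min(self) -> int:
        return int(np.min(self.null))

    @property
    def null_max(self) -> int:
        return int(np.max(self.null))

    @property
    def is_upper_bound(self) -> bool:
        """True when no null value reached the observed count."""
        return not bool((self.null >= self.observed).any())

    @property
    def p_value(self) -> float:
        """Two-tailed p: 2 x P(null >= observed), capped at 1.

        When the tail is empty the true p is below resolution and this is
        the upper bound 2/n_sims (see ``is_upper_bound``).
        """
        count = int((self.null >= self.observed).sum())
        if count == 0:
            return 2.0 / self.n_sims
        return min(1.0, 2.0 * count / self.n_sims)

    def p_string(self) -> str:
        return (f"< {2.0 / self.n_sims:g}" if self.is_upper_bound
                else f"{self.p_value:g}")


def _overlaps(start: int, end: int, intervals: list[Interval]) -> bool:
    return any(start < e and end > s for s, e in intervals)


def classify_chromatin(variant: CNVVariant | Interval,
                       het_intervals: dict[str, list[Interval]],
                       chrom: str | None = None) -> str:
    """'heterochromatic' if any part of the CNV overlaps heterochromatin.

    Intervals are 0-based half-open; a single base of overlap suffices,
    touching intervals do not overlap.
    """
    if isinstance(variant, CNVVariant):
        chrom, start, end = variant.chrom, variant.start, variant.end
    else:
        if chrom is None:
            raise ValueError("chrom required for a bare interval")
        start, end = variant
    hit = _overlaps(start, end, het_intervals.get(chrom, []))
    return "heterochromatic" if hit else "euchromatic"


def gene_kept_ranges(genes: pd.DataFrame, tracks: pd.DataFrame,
                     window_filter: WindowFilter) -> pd.DataFrame:
    """Per-gene kept-window summary used by the gene-content rules.

    For each gene: the number of windows it overlaps, how many of those are
    kept, whether the gene is retained (>= 50% of its windows kept), and
    the genomic extent of its kept windows.  A gene overlapping no window
    is not retained.
    """
    starts = tracks["start"].to_numpy()
    ends = tracks["end"].to_numpy()
    chroms = tracks["chrom"].to_numpy()
    keep = window_filter.keep
    rows = []
    for g in genes.itertuples(index=False):
        on_chrom = chroms == g.chrom
        overlap = on_chrom & (starts < g.end) & (ends > g.start)
        n_windows = int(overlap.sum())
        kept = overlap & keep
        n_kept = int(kept.sum())
        retained = n_windows > 0 and n_kept >= 0.5 * n_windows
        kept_idx = np.flatnonzero(kept)
        rows.append({
            "name": g.name,
            "chrom": g.chrom,
            "detox": bool(getattr(g, "detox", False)),
            "n_windows": n_windows,
            "n_kept": n_kept,
            "retained": retained,
            "kept_start": int(starts[kept_idx[0]]) if n_kept else -1,
            "kept_end": int(ends[kept_idx[-1]]) if n_kept else -1,
        })
    return pd.DataFrame(rows, columns=["name", "chrom", "detox", "n_windows",
                                       "n_kept", "retained", "kept_start",
                                       "kept_end"])


def genes_copied(variant: CNVVariant, genes: pd.DataFrame, tracks: pd.DataFrame,
                 window_filter: WindowFilter,
                 ranges: pd.DataFrame | None = None) -> list[str]:
    """Retained genes copied by a variant.

    A retained gene (>= 50% of its windows kept) is copied iff *all* its
    kept windows lie inside the variant's consensus coordinates.  Note the
    rule is applied literally: dropped windows extending beyond the variant
    do not disqualify a gene.
    """
    if ranges is None:
        ranges = gene_kept_ranges(genes, tracks, window_filter)
    sel = ranges[(ranges["chrom"] == variant.chrom) & ranges["retained"]
                 & (ranges["n_kept"] > 0)]
    hit = sel[(sel["kept_start"] >= variant.start) & (sel["kept_end"] <= variant.end)]
    return hit["name"].tolist()


@dataclass
class PositionNullResult:
    heterochromatin: EnrichmentResult
    genic: EnrichmentResult


def _kept_window_count(variant: CNVVariant, starts: np.ndarray, ends: np.ndarray
                       ) -> int:
    return int(((starts < variant.end) & (ends > variant.start)).sum())


def simulate_position_null(
    variants: list[CNVVariant],
    tracks: pd.DataFrame,
    window_filter: WindowFilter,
    het_intervals: dict[str, list[Interval]],
    genes: pd.DataFrame,
    n_sims: int = 10_000,
    seed: int = 0,
    *,
    euchromatin_only: bool = False,
) -> PositionNullResult:
    """Re-place every variant uniformly, keeping its kept-window footprint.

    Each variant covering k kept windows is moved to a uniformly random run
    of k consecutive kept windows on its own chromosome; per simulation the
    number of variants overlapping heterochromatin and the number
    containing at least one retained gene are recorded.  With
    ``euchromatin_only`` placements overlapping heterochromatin are
    excluded from the admissible set (used after restricting ``variants``
    to euchromatic ones).
    """
    rng = np.random.default_rng(seed)
    ranges = gene_kept_ranges(genes, tracks, window_filter)

    # per-chromosome kept-window coordinate arrays
    chrom_kept: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in tracks["chrom"].unique():
        idx = window_filter.kept_indices((tracks["chrom"] == chrom).to_numpy())
        chrom_kept[chrom] = (tracks["start"].to_numpy()[idx],
                             tracks["end"].to_numpy()[idx])

    het_flags = []
    gene_flags = []
    observed_het = 0
    observed_genic = 0
    for v in variants:
        if v.chrom not in chrom_kept:
            raise ValueError(f"variant {v.variant_id} on unknown chromosome {v.chrom}")
        starts, ends = chrom_kept[v.chrom]
        k = _kept_window_count(v, starts, ends)
        if k < 1 or k > len(starts):
            raise ValueError(
                f"variant {v.variant_id} covers {k} kept windows; no placement fits")
        n_place = len(starts) - k + 1
        place_start = starts[:n_place]
        place_end = ends[k - 1:]
        het = np.array([_overlaps(s, e, het_intervals.get(v.chrom, []))
                        for s, e in zip(place_start, place_end)])
        sel = ranges[(ranges["chrom"] == v.chrom) & ranges["retained"]
                     & (ranges["n_kept"] > 0)]
        gs = sel["kept_start"].to_numpy()
        ge = sel["kept_end"].to_numpy()
        genic = np.array([bool(((gs >= s) & (ge <= e)).any())
                          for s, e in zip(place_start, place_end)])
        if euchromatin_only:
            admissible = np.flatnonzero(~het)
            if admissible.size == 0:
                raise ValueError(
                    f"variant {v.variant_id}: no euchromatic placement fits")
        else:
            admissible = np.arange(n_place)
        draws = admissible[rng.integers(0, len(admissible), n_sims)]
        het_flags.append(het[draws])
        gene_flags.append(genic[draws])
        observed_het += _overlaps(v.start, v.end, het_intervals.get(v.chrom, []))
        observed_genic += bool(genes_copied(v, genes, tracks, window_filter, ranges))

    null_het = np.sum(het_flags, axis=0).astype(int) if het_flags else \
        np.zeros(n_sims, dtype=int)
    null_genic = np.sum(gene_flags, axis=0).astype(int) if gene_flags else \
        np.zeros(n_sims, dtype=int)
    return PositionNullResult(
        heterochromatin=EnrichmentResult(observed_het, null_het),
        genic=EnrichmentResult(observed_genic, null_genic),
    )


def simulate_gene_identity_null(
    genic_variants: list[CNVVariant],
    genes: pd.DataFrame,
    tracks: pd.DataFrame,
    window_filter: WindowFilter,
    n_sims: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Detox-gene enrichment among gene-containing CNVs.

    Each genic variant covers a run of k consecutive (retained) genes; the
    null reassigns it a uniformly random run of k consecutive genes in
    genomic order, never crossing a chromosome boundary, and counts the
    variants containing at least one metabolic detox gene.  A CNV counts
    once however many detox genes it holds.
    """
    rng = np.random.default_rng(seed)
    ranges = gene_kept_ranges(genes, tracks, window_filter)
    retained = ranges[ranges["retained"]].reset_index(drop=True)

    # genomic gene order per chromosome, with detox flags
    detox_by_chrom = {
        chrom: grp["detox"].to_numpy()
        for chrom, grp in retained.groupby("chrom", sort=False)
    }

    observed = 0
    run_lengths = []
    for v in genic_variants:
        copied = genes_copied(v, genes, tracks, window_filter, ranges)
        k = len(copied)
        if k == 0:
            raise ValueError(f"variant {v.variant_id} contains no retained gene")
        run_lengths.append(k)
        flags = retained.set_index("name").loc[copied, "detox"]
        observed += bool(flags.any())

    null = np.zeros(n_sims, dtype=int)
    for k in run_lengths:
        # all admissible runs of k consecutive genes, across chromosomes
        hits = []
        for flags in detox_by_chrom.values():
            if len(flags) < k:
                continue
            csum = np.concatenate([[0], np.cumsum(flags)])
            hits.append((csum[k:] - csum[:-k]) > 0)
        if not hits:
            raise ValueError(f"no chromosome holds a run of {k} consecutive genes")
        hit = np.concatenate(hits)
        null += hit[rng.integers(0, len(hit), n_sims)]
    return EnrichmentResult(observed, null)


@dataclass
class SizeComparison:
    statistic: float  # rank-sum W (Mann-Whitney U of the first group)
    p_value: float
    n1: int
    n2: int
    median1: float
    median2: float


def compare_sizes(group1: list[CNVVariant] | np.ndarray,
                  group2: list[CNVVariant] | np.ndarray) -> SizeComparison:
    """Two-sided Wilcoxon rank-sum test on CNV lengths (bp)."""
    def lengths(group):
        if len(group) and isinstance(group[0], CNVVariant):
            return np.asarray([v.length for v in group], dtype=float)
        return np.asarray(group, dtype=float)

    x, y = lengths(group1), lengths(group2)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return SizeComparison(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n1=len(x), n2=len(y),
        median1=float(np.median(x)), median2=float(np.median(y)),
    )


def fisher_contingency(table: np.ndarray, *, n_replicates: int = 10**6,
                       seed: int = 0) -> float:
    """Fisher's exact test p-value for an r x c contingency table.

    2x2 tables are tested exactly; larger tables use a Monte-Carlo p-value
    (tables drawn under fixed margins via the Patefield algorithm, tail
    defined by table probability), as in R's simulated p-value option.
    Margins being fixed, tables are probability-ordered by
    ``-sum(lgamma(x + 1))`` over their cells.
    """
    from scipy.special import gammaln

    table = np.asarray(table, dtype=int)
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    sims = dist.rvs(n_replicates, method="patefield", random_state=rng)
    logp_obs = -gammaln(table + 1.0).sum()
    logp_sim = -gammaln(sims + 1.0).sum(axis=(1, 2))
    count = int((logp_sim <= logp_obs + 1e-7).sum())
    return (1 + count) / (1 + n_replicates)
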