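"""Haplotype-based selection signals around CNV alleles.

A CNV allele spreading by positive selection rides a recent common
haplotype, so haplotypes carrying it stay identical over longer distances
than wild-type haplotypes from the same population.  Three views of this
signal are provided: extended haplotype homozygosity (EHH) decay on each
side of the CNV-containing region, the distribution of pairwise shared
haplotype lengths with a bootstrap confidence interval on the median, and
hierarchical clustering of haplotypes (for CNVs whose zygosity cannot be
phased), whose major clusters can be tested for association with allele
copy numbers at the sample level.

SNPs inside the CNV-containing region are excluded from all calculations:
read mapping and genotyping inside an amplification are unreliable, and
the region boundary serves as the core edge from which homozygosity is
measured outward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "HaplotypeMatrix",
    "EHHCurve",
    "SharedLengthDistribution",
    "compute_ehh",
    "shared_haplotype_lengths",
    "cluster_haplotypes",
    "cluster_counts_per_sample",
    "AssociationReport",
    "associate_cluster_with_cnv",
]


@dataclass
class HaplotypeMatrix:
    """Phased biallelic haplotypes with positions and core-allele labels.

    ``core`` assigns each haplotype to 'WT', a CNV allele id, or 'excluded'
    (haplotypes carrying more than one CNV allele are excluded upstream).
    ``sample_ids`` (optional) maps each haplotype to its diploid sample.
    """

    haplotypes: np.ndarray  # (n_haplotypes, n_variants) in {0, 1}
    positions: np.ndarray   # bp, strictly increasing
    accessible: np.ndarray | None = None
    core: np.ndarray | None = None
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if len(self.positions) != self.haplotypes.shape[1]:
            raise ValueError("positions do not match haplotype columns")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.accessible is None:
            self.accessible = np.ones(len(self.positions), dtype=bool)
        if self.core is None:
            self.core = np.array(["WT"] * self.haplotypes.shape[0], dtype=object)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def carriers(self, core_label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.core) == core_label)


@dataclass
class EHHCurve:
    """EHH values at increasing distances from the core-region edge."""

    direction: str  # 'left' or 'right'
    distances: np.ndarray  # bp from the core edge; starts at 0
    ehh: np.ndarray        # EHH(0) = 1, non-increasing

    def __post_init__(self) -> None:
        assert self.ehh[0] == 1.0 and np.all(np.diff(self.ehh) <= 1e-12)

    def at(self, distance: float) -> float:
        """EHH at the last variant no farther than ``distance``."""
        i = int(np.searchsorted(self.distances, distance, side="right")) - 1
        return float(self.ehh[max(i, 0)])


def _ordered_side(hap: HaplotypeMatrix, cnv_region: tuple[int, int],
                  direction: str) -> tuple[np.ndarray, np.ndarray]:
    """Variant columns on one side of the region, nearest first, with distances."""
    left_edge, right_edge = cnv_region
    pos = hap.positions
    if direction == "left":
        idx = np.flatnonzero(pos < left_edge)[::-1]
        dist = left_edge - pos[idx]
    else:
        idx = np.flatnonzero(pos > right_edge)
        dist = pos[idx] - right_edge
    return idx, dist


def compute_ehh(
    hap: HaplotypeMatrix,
    core_label: str,
    cnv_region: tuple[int, int],
    max_distance: float | None = None,
) -> dict[str, EHHCurve]:
    """EHH decay for one core allele, leftward and rightward of the region.

    EHH at distance x is the fraction of unordered pairs of core-carrying
    haplotypes identical at every included variant between the core edge
    and x.  Variants inside ``cnv_region`` are masked out.  Returns
    ``{'left': EHHCurve, 'right': EHHCurve}``.
    """
    rows = hap.carriers(core_label)
    if len(rows) < 2:
        raise ValueError(f"need >= 2 haplotypes with core {core_label!r}")
    n_pairs = len(rows) * (len(rows) - 1) // 2
    out = {}
    for direction in ("left", "right"):
        idx, dist = _ordered_side(hap, cnv_region, direction)
        if max_distance is not None:
            keep = dist <= max_distance
            idx, dist = idx[keep], dist[keep]
        # refine the partition of carriers variant by variant
        groups = [rows]
        distances = [0.0]
        ehh = [1.0]
        for col, d in zip(idx, dist):
            new_groups = []
            for g in groups:
                if len(g) < 2:
                    continue
                alleles = hap.haplotypes[g, col]
                g0 = g[alleles == 0]
                g1 = g[alleles == 1]
                new_groups.extend(g for g in (g0, g1) if len(g) >= 2)
            groups = new_groups
            same = sum(len(g) * (len(g) - 1) // 2 for g in groups)
            distances.append(float(d))
            ehh.append(same / n_pairs)
        out[direction] = EHHCurve(direction, np.array(distances), np.array(ehh))
    return out


@dataclass
class SharedLengthDistribution:
    core_label: str
    lengths: np.ndarray        # per unordered pair: left + right extents (bp)
    left_lengths: np.ndarray
    right_lengths: np.ndarray
    median: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.median = float(np.median(self.lengths))
        rng = np.random.default_rng(self.seed)
        n = len(self.lengths)
        draws = rng.integers(0, n, size=(self.n_boot, n))
        boot_medians = np.median(self.lengths[draws], axis=1)
        lo, hi = np.percentile(boot_medians, [2.5, 97.5])
        self.ci_low = float(min(lo, self.median))
        self.ci_high = float(max(hi, self.median))


def _side_lengths(H: np.ndarray, rows: np.ndarray, idx: np.ndarray,
                  dist: np.ndarray) -> np.ndarray:
    """Pairwise shared length on one side: distance to the last variant
    at which a pair is still concordant, scanning outward from the edge."""
    n = len(rows)
    if len(idx) == 0:
        return np.zeros(n * (n - 1) // 2)
    sub = H[np.ix_(rows, idx)]
    out = []
    for a in range(n):
        diff = sub[a + 1:] != sub[a]  # (n-a-1, m)
        any_diff = diff.any(axis=1)
        first_diff = np.where(any_diff, diff.argmax(axis=1), len(idx))
        lengths = np.where(first_diff == 0, 0.0, dist[first_diff - 1])
        out.append(lengths)
    return np.concatenate(out)


def shared_haplotype_lengths(
    hap: HaplotypeMatrix,
    core_label: str,
    cnv_region: tuple[int, int],
    *,
    n_boot: int = 1000,
    seed: int = 0,
) -> SharedLengthDistribution:
    """Pairwise shared-haplotype lengths around the CNV region.

    For each unordered pair of haplotypes with the given core label, extend
    outward from each side of the region to the first discordant variant;
    the side's shared length is the distance to the last concordant variant
    (zero when the nearest variant already differs, the full surveyed span
    when no variant differs).  The distribution reported sums the two
    sides; per-side arrays are retained.  The 95% CI of the median is a
    percentile bootstrap over pairs.
    """
    rows = hap.carriers(core_label)
    if len(rows) < 2:
        raise ValueError(f"need >= 2 haplotypes with core {core_label!r}")
    left = _side_lengths(hap.haplotypes, rows,
                         *_ordered_side(hap, cnv_region, "left"))
    right = _side_lengths(hap.haplotypes, rows,
                          *_ordered_side(hap, cnv_region, "right"))
    return SharedLengthDistribution(
        core_label=core_label, lengths=left + right,
        left_lengths=left, right_lengths=right, n_boot=n_boot, seed=seed,
    )


def cluster_haplotypes(
    hap: HaplotypeMatrix,
    n_variants: int = 1000,
    cutoff: float = 0.001,
    method: str = "complete",
) -> np.ndarray:
    """Hierarchical clustering of haplotypes by accessible-SNP mismatch.

    The distance between two haplotypes is the proportion of accessible
    variants (among the first ``n_variants`` columns) at which they differ.
    Flat clusters are cut at ``cutoff``; labels are integers from 1 by
    decreasing cluster size (ties broken by smallest member index), so
    cluster 1 is always the largest.
    """
    cols = np.flatnonzero(hap.accessible[:n_variants])
    if cols.size == 0:
        raise ValueError("no accessible variants among the first n_variants")
    if hap.n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    X = hap.haplotypes[:, cols]
    d = pdist(X, metric="hamming")
    Z = linkage(d, method=method)
    raw = fcluster(Z, t=cutoff, criterion="distance")
    # relabel by descending size, ties by first member index
    order = sorted(
        np.unique(raw),
        key=lambda c: (-int((raw == c).sum()), int(np.flatnonzero(raw == c)[0])),
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    return np.array([relabel[c] for c in raw])


def cluster_counts_per_sample(
    sample_ids: np.ndarray,
    labels: np.ndarray,
    cluster: int,
) -> pd.Series:
    """Number of haplotypes per sample assigned to ``cluster`` (0-2)."""
    df = pd.DataFrame({"sample_id": np.asarray(sample_ids),
                       "hit": np.asarray(labels) == cluster})
    return df.groupby("sample_id")["hit"].sum()


@dataclass
class AssociationReport:
    female_rho: float | None = None
    female_p: float | None = None
    female_slope: float | None = None
    male_p: float | None = None
    male_odds_ratio: float | None = None
    male_table: np.ndarray | None = None


def associate_cluster_with_cnv(
    cluster_counts: pd.Series | dict[str, int],
    copy_numbers: dict[str, int],
    sexes: dict[str, str],
) -> AssociationReport:
    """Sample-level association between a haplotype cluster and a CNV allele.

    On the X chromosome females carry 0-2 cluster haplotypes and males 0-1.
    Females: Spearman rank correlation between cluster haplotype count and
    allele copy number, plus the least-squares slope of copy number on
    cluster count (a slope of 0.5 cluster-per-copy geometry means two extra
    copies per swept chromosome, i.e. a triplication).  Males: 2x2 Fisher
    exact test of cluster presence against allele presence.
    """
    counts = dict(cluster_counts)
    report = AssociationReport()

    f_ids = [s for s in counts if sexes.get(s) == "F"]
    if len(f_ids) >= 3:
        x = np.array([counts[s] for s in f_ids], dtype=float)
        y = np.array([copy_numbers.get(s, 0) for s in f_ids], dtype=float)
        rho, p = stats.spearmanr(x, y)
        report.female_rho, report.female_p = float(rho), float(p)
        if np.var(y) > 0:
            slope = np.polyfit(y, x, 1)[0]  # cluster count per copy
            report.female_slope = float(slope)

    m_ids = [s for s in counts if sexes.get(s) == "M"]
    if m_ids:
        in_cluster = np.array([counts[s] > 0 for s in m_ids])
        has_cnv = np.array([copy_numbers.get(s, 0) > 0 for s in m_ids])
        table = np.array([
            [int((in_cluster & has_cnv).sum()), int((in_cluster & ~has_cnv).sum())],
            [int((~in_cluster & has_cnv).sum()), int((~in_cluster & ~has_cnv).sum())],
        ])
        odds, p = stats.fisher_exact(table)
        report.male_p = float(p)
        report.male_odds_ratio = float(odds)
        report.male_table = table
    return report
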