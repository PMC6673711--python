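"""CNV allele typing from discordant read pairs and breakpoint reads.

Distinct amplification events covering the same locus ("CNV alleles") are
told apart by the mapping pattern of read pairs that straddle their
breakpoints: tandem duplications produce pairs aligning facing away from
each other, tandem inversions produce pairs in the same orientation,
internal deletions produce properly-oriented pairs with an outsized
insert, and reads crossing a breakpoint soft-clip at it.  A declarative
`DiagnosticSignature` records the expected pattern and anchor coordinates
for one allele; an allele is called present in a sample when at least two
diagnostic reads support its signature.

Copy number per allele is estimated from the coverage steps it induces: a
sample's normalized coverage over the locus is modelled as baseline plus
the sum of per-allele copy gains over each allele's span, solved by
non-negative least squares and rounded to integers.  Alleles whose copy
number exceeds 2 cannot be phased into genotypes and are excluded, as are
alleles whose genotype counts violate Hardy-Weinberg equilibrium in a
population where they occur.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "InsertModel",
    "ReadPairRecord",
    "SoftClipRecord",
    "DiagnosticSignature",
    "AlleleCall",
    "classify_read_pair",
    "call_alleles",
    "presence_table",
    "AlleleCopyNumberTable",
    "estimate_allele_copy_numbers",
    "hwe_exact_test",
    "genotype_and_filter",
    "GenotypeReport",
    "clip_consensus",
    "breakpoint_clip_export",
]

# copy-number table flags
ROUNDED_25_TO_2 = "ROUNDED_25_TO_2"
CN_GT2 = "CN_GT2"
HWE_FAIL = "HWE_FAIL"
NON_IDENTIFIABLE = "NON_IDENTIFIABLE"

PATTERNS = ("face_away", "same_orientation", "long_insert", "crossmapped",
            "breakpoint_clip")


@dataclass(frozen=True)
class InsertModel:
    """Library insert-size distribution (mean and standard deviation)."""

    mean: float
    sd: float


@dataclass(frozen=True)
class ReadPairRecord:
    sample_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    insert_size: int
    mate_elsewhere: bool = False

    def __post_init__(self) -> None:
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValueError("strands must be '+' or '-'")


@dataclass(frozen=True)
class SoftClipRecord:
    sample_id: str
    chrom: str
    pos: int  # breakpoint candidate: position where clipping occurs
    seq: str  # the clipped-off bases
    side: str  # 'start': clipped bases precede the aligned part; 'end': follow

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("clipped sequence must be non-empty")
        if self.side not in ("start", "end"):
            raise ValueError("side must be 'start' or 'end'")


@dataclass(frozen=True)
class DiagnosticSignature:
    """Expected diagnostic-read pattern defining one CNV allele."""

    allele_id: str
    chrom: str
    pattern: str  # one of PATTERNS
    anchor1: int  # left breakpoint (bp)
    anchor2: int  # right breakpoint (bp)
    tol_pair: int = 300
    tol_clip: int = 10
    clip_consensus: str | None = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")


def classify_read_pair(pair: ReadPairRecord, insert_model: InsertModel,
                       z: float = 5.0) -> str:
    """Classify a read pair by its mapping pattern.

    crossmapped: mates on different chromosomes (or mate flagged as mapping
    elsewhere); same_orientation: equal strands; face_away: leftmost mate
    on the minus strand (mates point outward); long_insert: proper
    orientation but insert beyond mean + z*sd of the library; proper:
    everything else.
    """
    if pair.mate_elsewhere or pair.chrom1 != pair.chrom2:
        return "crossmapped"
    if pair.strand1 == pair.strand2:
        return "same_orientation"
    left_strand = pair.strand1 if pair.pos1 <= pair.pos2 else pair.strand2
    if left_strand == "-":
        return "face_away"
    if pair.insert_size > insert_model.mean + z * insert_model.sd:
        return "long_insert"
    return "proper"


@dataclass
class AlleleCall:
    sample_id: str
    allele_id: str
    n_pairs: int
    n_clips: int
    present: bool

    @property
    def n_support(self) -> int:
        return self.n_pairs + self.n_clips


def _pair_supports(pair: ReadPairRecord, sig: DiagnosticSignature,
                   insert_model: InsertModel) -> bool:
    if pair.chrom1 != sig.chrom:
        return False
    kind = classify_read_pair(pair, insert_model)
    if kind != sig.pattern:
        return False
    lo, hi = sorted((pair.pos1, pair.pos2))
    if sig.pattern == "long_insert":
        # the pair straddles an internal deletion: both mates inside the span
        return lo >= sig.anchor1 - sig.tol_pair and hi <= sig.anchor2 + sig.tol_pair
    # the rightmost mate's *start* sits up to a read length left of the
    # right breakpoint, so allow one read length (~150 bp) of slack there
    return (abs(lo - sig.anchor1) <= sig.tol_pair
            and abs(hi - sig.anchor2) <= sig.tol_pair + 150)


def _clip_supports(clip: SoftClipRecord, sig: DiagnosticSignature) -> bool:
    if clip.chrom != sig.chrom:
        return False
    return (abs(clip.pos - sig.anchor1) <= sig.tol_clip
            or abs(clip.pos - sig.anchor2) <= sig.tol_clip)


def call_alleles(
    pairs: list[ReadPairRecord],
    clips: list[SoftClipRecord],
    signatures: list[DiagnosticSignature],
    insert_model: InsertModel,
    samples: list[str] | None = None,
    min_diagnostic_reads: int = 2,
) -> list[AlleleCall]:
    """Record allele presence per sample from diagnostic reads.

    A read pair supports a signature when its classified pattern matches
    and its mate coordinates fall within the anchor tolerances; a
    soft-clipped read supports it when the clip position lies within the
    clip tolerance of either breakpoint.  An allele is present in a sample
    iff its supporting reads number at least ``min_diagnostic_reads``.
    """
    if samples is None:
        samples = sorted({r.sample_id for r in pairs}
                         | {c.sample_id for c in clips})
    calls = []
    for sig in signatures:
        for sample in samples:
            n_pairs = sum(1 for p in pairs
                          if p.sample_id == sample and _pair_supports(p, sig, insert_model))
            n_clips = sum(1 for c in clips
                          if c.sample_id == sample and _clip_supports(c, sig))
            calls.append(AlleleCall(
                sample_id=sample, allele_id=sig.allele_id,
                n_pairs=n_pairs, n_clips=n_clips,
                present=(n_pairs + n_clips) >= min_diagnostic_reads,
            ))
    return calls


def presence_table(calls: list[AlleleCall]) -> pd.DataFrame:
    """Samples x alleles boolean presence matrix."""
    df = pd.DataFrame([{
        "sample_id": c.sample_id, "allele_id": c.allele_id, "present": c.present,
    } for c in calls])
    return df.pivot(index="sample_id", columns="allele_id", values="present")


@dataclass
class AlleleCopyNumberTable:
    """Long-format allele-specific copy numbers with rounding provenance."""

    table: pd.DataFrame  # sample_id, allele_id, raw, copies, flags

    def copies_of(self, sample_id: str, allele_id: str) -> int:
        row = self.table[(self.table["sample_id"] == sample_id)
                         & (self.table["allele_id"] == allele_id)]
        return int(row["copies"].iloc[0]) if len(row) else 0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def estimate_allele_copy_numbers(
    norm_locus: np.ndarray,
    window_starts: np.ndarray,
    samples: list[str],
    presence: pd.DataFrame,
    spans: dict[str, tuple[int, int]],
    baselines: dict[str, int] | int = 2,
    *,
    single_high_raw_limit: float = 3.0,
) -> AlleleCopyNumberTable:
    """Estimate per-allele copy gains from coverage steps at a locus.

    ``norm_locus`` is normalized coverage over the locus's kept windows
    (samples x windows, aligned to ``window_starts``); ``presence`` is the
    samples x alleles boolean matrix from diagnostic-read calling;
    ``spans`` maps each allele to its genomic extent.  For each sample the
    model  E[cov(w)] = baseline + sum_a c_a * 1[w in span_a]  over its
    present alleles is solved for c_a >= 0 by non-negative least squares,
    and each c_a is rounded (half-up) to an integer copy count.

    Two alleles with identical window footprints in one sample make the
    solve non-identifiable; such rows are flagged NON_IDENTIFIABLE with NaN
    estimates.  Cohort-level rounding guard: if exactly one sample's
    rounded copies for an allele exceed 2 while its raw estimate stays
    below ``single_high_raw_limit``, that lone estimate is treated as noise
    and recorded as 2 with flag ROUNDED_25_TO_2.
    """
    norm_locus = np.atleast_2d(np.asarray(norm_locus, dtype=float))
    window_starts = np.asarray(window_starts)
    rows = []
    for i, sample in enumerate(samples):
        if sample in presence.index:
            present = [a for a in presence.columns
                       if a in spans and bool(presence.loc[sample, a])]
        else:
            present = []
        base = baselines if isinstance(baselines, int) else baselines.get(sample, 2)
        if not present:
            continue
        X = np.column_stack([
            ((window_starts >= spans[a][0]) & (window_starts < spans[a][1]))
            .astype(float) for a in present
        ])
        # identical footprints cannot be separated by coverage
        degenerate = False
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                if np.array_equal(X[:, a], X[:, b]):
                    degenerate = True
        finite = np.isfinite(norm_locus[i])
        if degenerate or not finite.any() or not X[finite].any(axis=0).all():
            for a in present:
                rows.append({"sample_id": sample, "allele_id": a,
                             "raw": np.nan, "copies": -1,
                             "flags": NON_IDENTIFIABLE})
            continue
        y = norm_locus[i, finite] - base
        coef, _ = nnls(X[finite], y)
        for a, c in zip(present, coef):
            rows.append({"sample_id": sample, "allele_id": a,
                         "raw": float(c), "copies": _round_half_up(float(c)),
                         "flags": ""})

    df = pd.DataFrame(rows, columns=["sample_id", "allele_id", "raw", "copies",
                                     "flags"])
    # single-sample near-2.5 guard, applied per allele across the cohort
    for allele in df["allele_id"].unique():
        sel = (df["allele_id"] == allele) & (df["copies"] > 2)
        if sel.sum() == 1:
            j = df.index[sel][0]
            if df.loc[j, "raw"] < single_high_raw_limit:
                df.loc[j, "copies"] = 2
                df.loc[j, "flags"] = ROUNDED_25_TO_2
    return AlleleCopyNumberTable(df)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Two-sided by probability ordering: the p-value sums, over all
    heterozygote counts compatible with the observed allele counts, the
    probabilities no larger than that of the observed configuration
    (Levene-Haldane conditional distribution).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_alt = n_het + 2 * n_hom_alt
    rare = min(n_alt, 2 * n - n_alt)

    def log_prob(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (math.lgamma(n + 1)
                - math.lgamma(hom_rare + 1) - math.lgamma(h + 1)
                - math.lgamma(hom_common + 1)
                + h * math.log(2)
                + math.lgamma(rare + 1) + math.lgamma(2 * n - rare + 1)
                - math.lgamma(2 * n + 1))

    hs = range(rare % 2, rare + 1, 2)
    logs = {h: log_prob(h) for h in hs}
    lobs = logs[n_het]
    total = sum(math.exp(lp) for lp in logs.values())
    p = sum(math.exp(lp) for lp in logs.values() if lp <= lobs + 1e-12) / total
    return min(1.0, p)


@dataclass
class GenotypeReport:
    genotypes: pd.DataFrame  # sample_id, allele_id, genotype (0/1/2)
    excluded: dict[str, str] = field(default_factory=dict)  # allele -> reason
    triplications: list[str] = field(default_factory=list)


def genotype_and_filter(
    copy_numbers: AlleleCopyNumberTable,
    manifest: pd.DataFrame,
    alpha: float = 0.05,
) -> GenotypeReport:
    """Convert allele copy numbers to genotypes and filter unreliable alleles.

    Copies of 1 mean heterozygote, 2 homozygote.  An allele with any sample
    above 2 copies (after the rounding guard) cannot be phased and is
    excluded (CN_GT2).  When every carrier of an allele has exactly 2
    copies and none has 1, the allele is a pure triplication: carriers are
    genotyped heterozygous.  Each allele is then tested for Hardy-Weinberg
    equilibrium within every population where it occurs (exact conditional
    test); an allele with p < ``alpha`` anywhere is excluded (HWE_FAIL).
    """
    df = copy_numbers.table
    pop_of = dict(zip(manifest["sample_id"], manifest["population"]))
    all_samples = manifest["sample_id"].tolist()
    genotype_rows = []
    excluded: dict[str, str] = {}
    triplications: list[str] = []

    for allele in df["allele_id"].unique():
        sub = df[df["allele_id"] == allele]
        if (sub["flags"] == NON_IDENTIFIABLE).any():
            excluded[allele] = NON_IDENTIFIABLE
            continue
        copies = dict(zip(sub["sample_id"], sub["copies"]))
        if any(c > 2 for c in copies.values()):
            excluded[allele] = CN_GT2
            continue
        carrier_copies = [c for c in copies.values() if c > 0]
        pure_triplication = (len(carrier_copies) > 0
                             and all(c == 2 for c in carrier_copies))
        geno = {}
        for s in all_samples:
            c = copies.get(s, 0)
            if pure_triplication:
                geno[s] = 1 if c == 2 else 0
            else:
                geno[s] = int(c)
        if pure_triplication:
            triplications.append(allele)

        # HWE within each population where the allele occurs
        failed = False
        pops_with_allele = {pop_of[s] for s, g in geno.items() if g > 0
                            if s in pop_of}
        for pop in pops_with_allele:
            members = [s for s in all_samples if pop_of[s] == pop]
            counts = Counter(geno[s] for s in members)
            p = hwe_exact_test(counts.get(0, 0), counts.get(1, 0), counts.get(2, 0))
            if p < alpha:
                failed = True
                break
        if failed:
            excluded[allele] = HWE_FAIL
            continue
        for s in all_samples:
            genotype_rows.append({"sample_id": s, "allele_id": allele,
                                  "genotype": geno[s]})

    genotypes = pd.DataFrame(genotype_rows,
                             columns=["sample_id", "allele_id", "genotype"])
    return GenotypeReport(genotypes=genotypes, excluded=excluded,
                          triplications=triplications)


def clip_consensus(clips: list[SoftClipRecord]) -> str:
    """Majority-rule consensus of clipped sequences from one breakpoint side.

    Sequences from the 'start' side end at the breakpoint and are aligned
    on their right edge; 'end'-side sequences start at the breakpoint and
    align on their left edge.  Positions covered by fewer than half the
    records are trimmed.
    """
    if not clips:
        raise ValueError("no clip records")
    side = clips[0].side
    seqs = [c.seq for c in clips]
    L = max(len(s) for s in seqs)
    if side == "start":
        seqs = [s.rjust(L, ".") for s in seqs]
    else:
        seqs = [s.ljust(L, ".") for s in seqs]
    out = []
    half = len(seqs) / 2.0
    for i in range(L):
        col = [s[i] for s in seqs if s[i] != "."]
        if len(col) < half:
            out.append(None)
            continue
        out.append(Counter(col).most_common(1)[0][0])
    return "".join(b for b in out if b is not None)


def breakpoint_clip_export(
    signatures: list[DiagnosticSignature],
    clips: list[SoftClipRecord],
    path: str,
) -> int:
    """Write per-breakpoint clip consensus sequences as FASTA.

    For each signature, clips within tolerance of each anchor are grouped
    by side and collapsed to a majority consensus; records are named
    ``allele_id/side``.  Returns the number of records written.
    """
    n = 0
    with open(path, "w") as fh:
        for sig in signatures:
            for side in ("start", "end"):
                group = [c for c in clips
                         if c.side == side and _clip_supports(c, sig)]
                if not group:
                    continue
                fh.write(f">{sig.allele_id}/{side}\n{clip_consensus(group)}\n")
                n += 1
    return n
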