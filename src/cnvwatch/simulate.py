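"""Synthetic cohort generator with known truth.

Emulates the data shapes of a population resequencing cohort: a windowed
reference annotation (GC%, accessibility, MQ0 fraction, heterochromatin,
gene models), per-sample windowed read counts with GC-dependent bias and
negative-binomial noise, discordant/soft-clipped reads around planted CNV
breakpoints, and phased haplotypes in which a CNV allele rides a swept core
haplotype.  Every generator is deterministic given its seed and returns (or
can write) a truth table, so each downstream stage of the pipeline can be
tested against known answers.

The generators work at the window level: no base-level sequence is
simulated and no reads are aligned.  Coverage noise is negative binomial
with a variance-to-mean ratio (``dispersion``) of at least 1; dispersion 1
is exactly Poisson.  The GC bias is a unimodal quadratic of GC percentage
peaking near 45%, mimicking the bias of Illumina libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alleles import (
    DiagnosticSignature,
    InsertModel,
    ReadPairRecord,
    SoftClipRecord,
)
from .coverage import CoverageMatrix
from .selection import HaplotypeMatrix

__all__ = [
    "SimulatedReference",
    "SimulatedSample",
    "PlantedCNV",
    "make_reference",
    "gc_factor",
    "true_copy_number",
    "simulate_window_counts",
    "simulate_breakpoint_reads",
    "simulate_background_reads",
    "signatures_for_planted",
    "simulate_swept_haplotypes",
    "truth_table",
    "DEFAULT_CHROM_SPEC",
]

#: desk-scale default genome: two autosomal arms and an X
DEFAULT_CHROM_SPEC = (("2R", 600_000), ("2L", 600_000), ("X", 300_000))

MECHANISMS = ("tandem_duplication", "tandem_inversion", "deletion_within_amplification")


@dataclass
class SimulatedReference:
    """Windowed reference annotation for a simulated genome."""

    chromosomes: list[tuple[str, int]]
    window_size: int
    tracks: pd.DataFrame  # chrom, start, end, gc, accessibility, mq0_frac
    heterochromatin: dict[str, list[tuple[int, int]]]
    genes: pd.DataFrame  # name, chrom, start, end, detox

    def n_windows(self, chrom: str | None = None) -> int:
        if chrom is None:
            return len(self.tracks)
        return int((self.tracks["chrom"] == chrom).sum())

    def chrom_offset(self, chrom: str) -> int:
        """Global index of the first window of ``chrom``."""
        idx = np.flatnonzero((self.tracks["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(chrom)
        return int(idx[0])

    def global_window(self, chrom: str, window: int) -> int:
        n = self.n_windows(chrom)
        if not 0 <= window < n:
            raise IndexError(f"window {window} out of range for {chrom} ({n} windows)")
        return self.chrom_offset(chrom) + window


@dataclass(frozen=True)
class SimulatedSample:
    sample_id: str
    population: str = "popA"
    sex: str = "F"
    mean_depth: float = 30.0
    dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.dispersion < 1:
            raise ValueError("dispersion (variance/mean) must be >= 1")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")

    def ploidy(self, chrom: str) -> int:
        return 1 if (chrom == "X" and self.sex == "M") else 2


@dataclass(frozen=True)
class PlantedCNV:
    """A CNV planted into one sample, with full truth."""

    sample_id: str
    chrom: str
    start_window: int
    end_window: int  # inclusive
    copies_added_per_chromosome: int = 1
    zygosity: int = 1  # number of chromosomes carrying the amplification
    mechanism: str = "tandem_duplication"
    allele_id: str = "allele"

    def __post_init__(self) -> None:
        if self.end_window < self.start_window:
            raise ValueError("end_window must be >= start_window")
        if self.copies_added_per_chromosome < 1:
            raise ValueError("copies_added_per_chromosome must be >= 1")
        if self.zygosity not in (1, 2):
            raise ValueError("zygosity must be 1 or 2")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    @property
    def n_windows(self) -> int:
        return self.end_window - self.start_window + 1

    def copies_added(self) -> int:
        return self.zygosity * self.copies_added_per_chromosome


def make_reference(
    seed: int,
    chrom_spec: tuple[tuple[str, int], ...] = DEFAULT_CHROM_SPEC,
    *,
    window_size: int = 300,
    gc_model: tuple[float, float] = (45.0, 8.0),
    het_fraction: float = 0.10,
    gene_density: float = 6.0,
    detox_fraction: float = 0.05,
    low_access_fraction: float = 0.05,
    mq0_high_fraction: float = 0.02,
) -> SimulatedReference:
    """Build a windowed reference annotation.

    GC% per window is drawn from a normal(mean, sd) given by ``gc_model``,
    rounded to the nearest percent and clipped to [0, 100] — so extreme GC
    bins are naturally rare, exercising the GC-rarity window filter.
    Heterochromatin (fraction ``het_fraction`` of each chromosome) is placed
    half at each chromosome end, mirroring pericentromeric/telomeric
    chromatin.  ``gene_density`` is gene models per 100 kb; a fraction
    ``detox_fraction`` of genes is flagged as metabolic detox genes.

    Deterministic given ``seed``; a trailing partial window is dropped from
    each chromosome.
    """
    rng = np.random.default_rng(seed)
    rows = []
    het: dict[str, list[tuple[int, int]]] = {}
    gene_rows = []
    gene_counter = 0
    for chrom, length in chrom_spec:
        n_win = length // window_size
        if n_win < 10:
            raise ValueError(f"chromosome {chrom!r} must span at least 10 windows")
        usable = n_win * window_size
        gc = np.clip(np.rint(rng.normal(gc_model[0], gc_model[1], n_win)), 0, 100)
        accessibility = np.ones(n_win)
        low = rng.random(n_win) < low_access_fraction
        accessibility[low] = rng.uniform(0.0, 0.9, low.sum())
        mq0 = rng.uniform(0.0, 0.01, n_win)
        high = rng.random(n_win) < mq0_high_fraction
        mq0[high] = rng.uniform(0.05, 0.40, high.sum())

        starts = np.arange(n_win) * window_size
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + window_size,
            "gc": gc.astype(int),
            "accessibility": accessibility,
            "mq0_frac": mq0,
        }))

        het_bp = int(round(het_fraction * usable / 2 / window_size)) * window_size
        intervals = []
        if het_bp > 0:
            intervals.append((0, het_bp))
            intervals.append((usable - het_bp, usable))
        het[chrom] = intervals

        n_genes = int(round(gene_density * usable / 100_000))
        if n_genes > 0:
            # lay genes left to right with random gaps; stop at chromosome end
            pos = int(rng.integers(0, 5 * window_size))
            for _ in range(n_genes):
                glen = int(rng.integers(1, 9)) * window_size - int(rng.integers(0, 100))
                gap = int(rng.integers(1, 6)) * window_size
                if pos + glen >= usable:
                    break
                gene_rows.append({
                    "name": f"gene{gene_counter:05d}",
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + glen,
                    "detox": bool(rng.random() < detox_fraction),
                })
                gene_counter += 1
                pos += glen + gap

    tracks = pd.concat(rows, ignore_index=True)
    genes = pd.DataFrame(gene_rows, columns=["name", "chrom", "start", "end", "detox"])
    return SimulatedReference(
        chromosomes=list(chrom_spec),
        window_size=window_size,
        tracks=tracks,
        heterochromatin=het,
        genes=genes,
    )


def gc_factor(gc: np.ndarray, *, strength: float = 0.5, peak: float = 45.0,
              floor: float = 0.05) -> np.ndarray:
    """Multiplicative GC coverage bias: quadratic, peaking at ``peak``%."""
    f = 1.0 - strength * ((np.asarray(gc, dtype=float) - peak) / 50.0) ** 2
    return np.maximum(f, floor)


def _check_planted(ref: SimulatedReference, samples: list[SimulatedSample],
                   planted: list[PlantedCNV]) -> None:
    by_id = {s.sample_id: s for s in samples}
    for cnv in planted:
        if cnv.sample_id not in by_id:
            raise ValueError(f"planted CNV references unknown sample {cnv.sample_id!r}")
        n = ref.n_windows(cnv.chrom)
        if cnv.end_window >= n:
            raise ValueError(
                f"planted CNV windows {cnv.start_window}-{cnv.end_window} exceed "
                f"{cnv.chrom} ({n} windows)"
            )
        s = by_id[cnv.sample_id]
        if cnv.chrom == "X" and s.sex == "M" and cnv.zygosity == 2:
            raise ValueError(
                f"CNV on X with zygosity 2 for male sample {s.sample_id!r}"
            )


def true_copy_number(ref: SimulatedReference, samples: list[SimulatedSample],
                     planted: list[PlantedCNV]) -> np.ndarray:
    """Truth total copy number per sample per window (float array)."""
    _check_planted(ref, samples, planted)
    chroms = ref.tracks["chrom"].to_numpy()
    cn = np.empty((len(samples), len(ref.tracks)))
    for i, s in enumerate(samples):
        cn[i] = np.where(chroms == "X", s.ploidy("X"), 2)
    index = {s.sample_id: i for i, s in enumerate(samples)}
    for cnv in planted:
        i = index[cnv.sample_id]
        g0 = ref.global_window(cnv.chrom, cnv.start_window)
        g1 = ref.global_window(cnv.chrom, cnv.end_window)
        cn[i, g0:g1 + 1] += cnv.copies_added()
    return cn


def simulate_window_counts(
    ref: SimulatedReference,
    samples: list[SimulatedSample],
    planted: list[PlantedCNV],
    seed: int,
    *,
    gc_bias_strength: float = 0.5,
) -> CoverageMatrix:
    """Draw raw windowed read counts for a cohort.

    The expected count of sample *s* at window *w* is::

        mean_depth(s) * gc_factor(gc_w) * CN(s, w) / 2

    where CN is the truth total copy number (diploid baseline 2 on
    autosomes; 1 on the male X).  Counts are negative binomial with
    variance ``dispersion * mean`` (Poisson at dispersion 1).
    """
    rng = np.random.default_rng(seed)
    cn = true_copy_number(ref, samples, planted)
    f = gc_factor(ref.tracks["gc"].to_numpy(), strength=gc_bias_strength)
    counts = np.zeros_like(cn, dtype=np.int64)
    for i, s in enumerate(samples):
        mean = s.mean_depth * f * cn[i] / 2.0
        if s.dispersion <= 1.0:
            counts[i] = rng.poisson(mean)
        else:
            # NB(r, p): mean = r(1-p)/p, var = mean/p  ->  p = 1/d
            p = 1.0 / s.dispersion
            r = mean * p / (1.0 - p)
            pos = r > 0
            draw = np.zeros_like(mean)
            draw[pos] = rng.negative_binomial(r[pos], p)
            counts[i] = draw
    return CoverageMatrix(
        samples=[s.sample_id for s in samples],
        tracks=ref.tracks,
        counts=counts,
        sex={s.sample_id: s.sex for s in samples},
    )


def _bp_span(ref: SimulatedReference, cnv: PlantedCNV) -> tuple[int, int]:
    w = ref.window_size
    return cnv.start_window * w, (cnv.end_window + 1) * w


def _allele_clip_seqs(allele_id: str, read_length: int) -> tuple[str, str]:
    """Deterministic per-allele clipped sequences for the two breakpoint sides."""
    rng = np.random.default_rng(abs(hash(allele_id)) % (2**31))
    bases = np.array(list("ACGT"))
    n = max(20, read_length // 3)
    left = "".join(rng.choice(bases, n))
    right = "".join(rng.choice(bases, n))
    return left, right


def simulate_breakpoint_reads(
    ref: SimulatedReference,
    planted: list[PlantedCNV],
    insert_model: InsertModel,
    read_length: int = 100,
    seed: int = 0,
    *,
    mean_diagnostic_reads: float = 6.0,
    min_diagnostic_reads: int = 2,
) -> tuple[list[ReadPairRecord], list[SoftClipRecord]]:
    """Emit discordant read pairs and breakpoint soft-clips for planted CNVs.

    Tandem duplications yield face-away pairs anchored at the two
    breakpoints (leftmost mate on the minus strand); tandem inversions yield
    same-orientation pairs; deletions within an amplification yield
    properly-oriented pairs with an insert far beyond the library insert
    distribution.  Each planted CNV also produces soft-clipped reads at both
    breakpoints whose clipped bases are a deterministic per-allele sequence.
    Every planted allele gets at least ``min_diagnostic_reads`` pairs.
    """
    if insert_model.mean <= 2 * read_length:
        raise ValueError("insert mean must exceed twice the read length")
    rng = np.random.default_rng(seed)
    pairs: list[ReadPairRecord] = []
    clips: list[SoftClipRecord] = []
    for cnv in planted:
        s_bp, e_bp = _bp_span(ref, cnv)
        n_reads = max(min_diagnostic_reads, int(rng.poisson(mean_diagnostic_reads)))
        for _ in range(n_reads):
            j1 = int(rng.integers(0, 150))
            j2 = int(rng.integers(0, 150))
            if cnv.mechanism == "tandem_duplication":
                pos1, strand1 = s_bp + j1, "-"
                pos2, strand2 = e_bp - read_length - j2, "+"
            elif cnv.mechanism == "tandem_inversion":
                pos1, strand1 = s_bp + j1, "+"
                pos2, strand2 = e_bp - read_length - j2, "+"
            else:  # deletion_within_amplification: long-insert proper pair
                gap = insert_model.mean + 8 * insert_model.sd + rng.integers(0, 300)
                mid = (s_bp + e_bp) // 2
                pos1, strand1 = mid - int(gap) // 2, "+"
                pos2, strand2 = mid + int(gap) // 2, "-"
            pairs.append(ReadPairRecord(
                sample_id=cnv.sample_id,
                chrom1=cnv.chrom, pos1=int(min(pos1, pos2)),
                strand1=strand1 if pos1 <= pos2 else strand2,
                chrom2=cnv.chrom, pos2=int(max(pos1, pos2)),
                strand2=strand2 if pos1 <= pos2 else strand1,
                insert_size=int(abs(pos2 - pos1)) + read_length,
            ))
        left_seq, right_seq = _allele_clip_seqs(cnv.allele_id, read_length)
        n_clips = max(1, n_reads // 2)
        for _ in range(n_clips):
            clips.append(SoftClipRecord(
                sample_id=cnv.sample_id, chrom=cnv.chrom,
                pos=s_bp + int(rng.integers(-5, 6)), seq=left_seq, side="start",
            ))
            clips.append(SoftClipRecord(
                sample_id=cnv.sample_id, chrom=cnv.chrom,
                pos=e_bp + int(rng.integers(-5, 6)), seq=right_seq, side="end",
            ))
    return pairs, clips


def simulate_background_reads(
    ref: SimulatedReference,
    sample_ids: list[str],
    insert_model: InsertModel,
    read_length: int = 100,
    n_pairs_per_sample: int = 200,
    discordant_fraction: float = 0.02,
    seed: int = 0,
) -> list[ReadPairRecord]:
    """Non-diagnostic read-pair background.

    Mostly properly-oriented pairs with library-distributed inserts, plus a
    small fraction of stray discordant pairs at uniformly random positions
    (chimeras, mapping artifacts).  Because stray pairs land anywhere, the
    chance of two of them mimicking the same breakpoint signature is
    negligible — they exercise the specificity of allele calling.
    """
    rng = np.random.default_rng(seed)
    chroms = [(c, (l // ref.window_size) * ref.window_size)
              for c, l in ref.chromosomes]
    pairs: list[ReadPairRecord] = []
    for sample in sample_ids:
        for _ in range(n_pairs_per_sample):
            chrom, length = chroms[rng.integers(0, len(chroms))]
            if rng.random() < discordant_fraction:
                kind = rng.choice(["face_away", "same_orientation",
                                   "long_insert", "crossmapped"])
                pos1 = int(rng.integers(0, length - 2000))
                gap = int(rng.integers(200, 1500))
                if kind == "face_away":
                    s1, s2 = "-", "+"
                elif kind == "same_orientation":
                    s1, s2 = "+", "+"
                elif kind == "long_insert":
                    s1, s2 = "+", "-"
                    gap = int(insert_model.mean + 8 * insert_model.sd
                              + rng.integers(0, 2000))
                else:
                    other = chroms[rng.integers(0, len(chroms))][0]
                    pairs.append(ReadPairRecord(
                        sample, chrom, pos1, "+", other,
                        int(rng.integers(0, length - 200)), "-",
                        insert_size=0))
                    continue
                pairs.append(ReadPairRecord(
                    sample, chrom, pos1, s1, chrom, pos1 + gap, s2,
                    insert_size=gap + read_length))
            else:
                insert = max(2 * read_length,
                             int(rng.normal(insert_model.mean, insert_model.sd)))
                pos1 = int(rng.integers(0, max(1, length - insert - 1)))
                pairs.append(ReadPairRecord(
                    sample, chrom, pos1, "+", chrom,
                    pos1 + insert - read_length, "-", insert_size=insert))
    return pairs


_PATTERN_FOR_MECHANISM = {
    "tandem_duplication": "face_away",
    "tandem_inversion": "same_orientation",
    "deletion_within_amplification": "long_insert",
}


def signatures_for_planted(
    ref: SimulatedReference,
    planted: list[PlantedCNV],
    *,
    tol_pair: int = 300,
    tol_clip: int = 10,
) -> list[DiagnosticSignature]:
    """Diagnostic signatures matching the reads the simulator emits.

    One signature per distinct allele_id; anchors are the planted breakpoint
    coordinates.
    """
    out: dict[str, DiagnosticSignature] = {}
    for cnv in planted:
        if cnv.allele_id in out:
            continue
        s_bp, e_bp = _bp_span(ref, cnv)
        left_seq, _ = _allele_clip_seqs(cnv.allele_id, 100)
        out[cnv.allele_id] = DiagnosticSignature(
            allele_id=cnv.allele_id,
            chrom=cnv.chrom,
            pattern=_PATTERN_FOR_MECHANISM[cnv.mechanism],
            anchor1=s_bp,
            anchor2=e_bp,
            tol_pair=tol_pair,
            tol_clip=tol_clip,
            clip_consensus=left_seq,
        )
    return list(out.values())


def simulate_swept_haplotypes(
    n_haplotypes: int,
    n_snps: int,
    sweep_allele_frequency: float,
    core_identity_length: float | None = 200_000.0,
    mutation_rate: float = 0.0,
    seed: int = 0,
    *,
    region_length: int = 1_000_000,
    cnv_region: tuple[int, int] | None = None,
    allele_id: str = "Dup1",
    inaccessible_fraction: float = 0.0,
) -> tuple[HaplotypeMatrix, np.ndarray]:
    """Simulate haplotypes in which a CNV allele rides a swept core.

    Carrier haplotypes (a fraction ``sweep_allele_frequency``) descend from
    a single founder: on each side of the CNV region they copy the founder
    out to an exponentially-distributed break distance with mean
    ``core_identity_length`` (``None`` = unbroken identity), with per-site
    flip probability ``mutation_rate`` inside the copied core; beyond the
    break they revert to independent draws from the population allele
    frequencies, as do wild-type haplotypes throughout.

    Returns the haplotype matrix (with per-haplotype core assignment) and
    the boolean truth carrier vector.
    """
    if not 0.0 <= sweep_allele_frequency <= 1.0:
        raise ValueError("sweep_allele_frequency must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if cnv_region is None:
        mid = region_length // 2
        cnv_region = (mid - 15_000, mid + 15_000)
    positions = np.sort(rng.choice(region_length, size=n_snps, replace=False))
    freqs = rng.uniform(0.05, 0.95, n_snps)
    H = (rng.random((n_haplotypes, n_snps)) < freqs).astype(np.uint8)

    n_carriers = int(round(sweep_allele_frequency * n_haplotypes))
    carriers = np.zeros(n_haplotypes, dtype=bool)
    carriers[rng.choice(n_haplotypes, size=n_carriers, replace=False)] = True
    founder = (rng.random(n_snps) < freqs).astype(np.uint8)

    left_edge, right_edge = cnv_region
    dist = np.where(positions < left_edge, left_edge - positions,
                    np.where(positions > right_edge, positions - right_edge, 0))
    for i in np.flatnonzero(carriers):
        if core_identity_length is None:
            core = np.ones(n_snps, dtype=bool)
        else:
            break_left = rng.exponential(core_identity_length)
            break_right = rng.exponential(core_identity_length)
            core = np.where(positions < left_edge, dist <= break_left,
                            dist <= break_right)
        H[i, core] = founder[core]
        if mutation_rate > 0:
            flips = core & (rng.random(n_snps) < mutation_rate)
            H[i, flips] ^= 1

    accessible = rng.random(n_snps) >= inaccessible_fraction
    core_labels = np.where(carriers, allele_id, "WT")
    hap = HaplotypeMatrix(
        haplotypes=H,
        positions=positions,
        accessible=accessible,
        core=core_labels.astype(object),
    )
    return hap, carriers


def truth_table(planted: list[PlantedCNV]) -> pd.DataFrame:
    """Planted-CNV truth as a plain table (one row per planted CNV)."""
    return pd.DataFrame([{
        "sample_id": c.sample_id,
        "chrom": c.chrom,
        "start_window": c.start_window,
        "end_window": c.end_window,
        "n_windows": c.n_windows,
        "copies_added": c.copies_added(),
        "zygosity": c.zygosity,
        "mechanism": c.mechanism,
        "allele_id": c.allele_id,
    } for c in planted])
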