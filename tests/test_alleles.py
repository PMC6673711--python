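import math

import numpy as np
import pandas as pd
import pytest

from cnvwatch import alleles as al
from cnvwatch import simulate as sim

INSERT = al.InsertModel(mean=400, sd=50)


def pair(pos1, strand1, pos2, strand2, chrom2="2R", mate_elsewhere=False,
         insert=None, sample="s0"):
    if insert is None:
        insert = abs(pos2 - pos1) + 100
    return al.ReadPairRecord(sample, "2R", pos1, strand1, chrom2, pos2, strand2,
                             insert, mate_elsewhere)


class TestClassifyReadPair:
    def test_face_away(self):
        assert al.classify_read_pair(pair(1000, "-", 1100, "+"), INSERT) == \
            "face_away"

    def test_same_orientation(self):
        assert al.classify_read_pair(pair(1000, "+", 1100, "+"), INSERT) == \
            "same_orientation"

    def test_long_insert(self):
        p = pair(1000, "+", 2000, "-", insert=1100)
        assert al.classify_read_pair(p, INSERT) == "long_insert"

    def test_proper(self):
        p = pair(1000, "+", 1300, "-", insert=400)
        assert al.classify_read_pair(p, INSERT) == "proper"

    def test_crossmapped(self):
        assert al.classify_read_pair(pair(1000, "+", 50, "-", chrom2="3L"),
                                     INSERT) == "crossmapped"
        assert al.classify_read_pair(pair(1000, "+", 1300, "-",
                                          mate_elsewhere=True), INSERT) == \
            "crossmapped"

    def test_orientation_independent_of_mate_order(self):
        a = pair(1000, "-", 1100, "+")
        b = pair(1100, "+", 1000, "-")
        assert al.classify_read_pair(a, INSERT) == \
            al.classify_read_pair(b, INSERT) == "face_away"


class TestCallAlleles:
    def setup_sig(self):
        return al.DiagnosticSignature("DupA", "2R", "face_away", 3000, 6300)

    def reads(self, n, sample="s0"):
        return [pair(3000 + i, "-", 6150 + i, "+", sample=sample)
                for i in range(n)]

    def test_one_read_is_not_enough(self):
        calls = al.call_alleles(self.reads(1), [], [self.setup_sig()], INSERT)
        assert not calls[0].present and calls[0].n_support == 1

    def test_two_reads_call_presence(self):
        calls = al.call_alleles(self.reads(2), [], [self.setup_sig()], INSERT)
        assert calls[0].present

    def test_monotone_in_read_depth(self):
        sig = self.setup_sig()
        prev = False
        for n in range(0, 6):
            present = al.call_alleles(self.reads(n), [], [sig], INSERT,
                                      samples=["s0"])[0].present
            assert present >= prev
            prev = present

    def test_reads_outside_anchor_tolerance_ignored(self):
        sig = self.setup_sig()
        far = [pair(9000, "-", 12_000, "+") for _ in range(5)]
        calls = al.call_alleles(far, [], [sig], INSERT)
        assert calls[0].n_support == 0

    def test_simulator_roundtrip_sensitivity_specificity(self):
        ref = sim.make_reference(1, (("2R", 300_000),))
        carriers = [sim.SimulatedSample(f"c{i}") for i in range(25)]
        noncarriers = [sim.SimulatedSample(f"n{i}") for i in range(25)]
        planted = [sim.PlantedCNV(s.sample_id, "2R", 300, 320, allele_id="DupA")
                   for s in carriers]
        pairs, clips = sim.simulate_breakpoint_reads(ref, planted, INSERT, seed=2)
        sigs = sim.signatures_for_planted(ref, planted)
        names = [s.sample_id for s in carriers + noncarriers]
        calls = al.call_alleles(pairs, clips, sigs, INSERT, samples=names)
        present = {c.sample_id for c in calls if c.present}
        assert present == {s.sample_id for s in carriers}


class TestCopyNumberEstimation:
    def run(self, profiles, spans, present, starts=None, **kw):
        samples = list(profiles)
        norm = np.vstack([profiles[s] for s in samples])
        if starts is None:
            starts = np.arange(norm.shape[1]) * 300
        pres = pd.DataFrame(present, index=samples).fillna(False)
        return al.estimate_allele_copy_numbers(norm, starts, samples, pres,
                                               spans, **kw)

    def test_single_allele_exact_step(self):
        prof = {"s0": np.r_[np.full(5, 2.0), np.full(10, 4.0), np.full(5, 2.0)]}
        spans = {"A": (5 * 300, 15 * 300)}
        t = self.run(prof, spans, {"A": {"s0": True}})
        assert t.copies_of("s0", "A") == 2

    def test_nested_alleles_resolved(self):
        # coverage 2 / 3 / 5 / 3 / 2: outer allele +1 over windows 5..25,
        # inner +2 over windows 10..20
        prof = np.full(30, 2.0)
        prof[5:25] += 1.0
        prof[10:20] += 2.0
        spans = {"outer": (5 * 300, 25 * 300), "inner": (10 * 300, 20 * 300)}
        t = self.run({"s0": prof}, spans,
                     {"outer": {"s0": True}, "inner": {"s0": True}})
        assert t.copies_of("s0", "outer") == 1
        assert t.copies_of("s0", "inner") == 2

    def test_three_overlapping_alleles_recovered_exactly(self):
        prof = np.full(40, 2.0)
        spans = {"a": (0, 6000), "b": (3000, 9000), "c": (6000, 12_000)}
        gains = {"a": 1, "b": 2, "c": 1}
        for name, (lo, hi) in spans.items():
            prof[lo // 300:hi // 300] += gains[name]
        t = self.run({"s0": prof}, spans,
                     {a: {"s0": True} for a in spans})
        for name, g in gains.items():
            assert t.copies_of("s0", name) == g

    def test_single_sample_at_two_point_five_rounded_down(self):
        prof_high = np.r_[np.full(5, 2.0), np.full(10, 4.5), np.full(5, 2.0)]
        prof_low = np.r_[np.full(5, 2.0), np.full(10, 4.0), np.full(5, 2.0)]
        spans = {"A": (1500, 4500)}
        t = self.run({"s0": prof_high, "s1": prof_low, "s2": prof_low}, spans,
                     {"A": {"s0": True, "s1": True, "s2": True}})
        row = t.table[(t.table.sample_id == "s0") & (t.table.allele_id == "A")]
        assert row["copies"].iloc[0] == 2
        assert row["flags"].iloc[0] == al.ROUNDED_25_TO_2
        assert t.copies_of("s1", "A") == 2

    def test_identical_spans_flagged_non_identifiable(self):
        prof = np.r_[np.full(5, 2.0), np.full(10, 6.0), np.full(5, 2.0)]
        spans = {"A": (1500, 4500), "B": (1500, 4500)}
        t = self.run({"s0": prof}, spans,
                     {"A": {"s0": True}, "B": {"s0": True}})
        assert (t.table["flags"] == al.NON_IDENTIFIABLE).all()

    def test_noisy_recovery_rate(self):
        """Integer copies recovered from realistically noisy coverage."""
        rng = np.random.default_rng(5)
        spans = {"A": (1500, 4500)}
        ok = 0
        reps = 200
        for _ in range(reps):
            cn = np.full(20, 2.0)
            cn[5:15] += 2  # one allele, 2 extra copies
            mean = 30 * cn / 2
            counts = rng.negative_binomial(mean, 0.5)  # dispersion 2
            norm = 2 * counts / 30
            t = self.run({"s0": norm}, spans, {"A": {"s0": True}})
            ok += t.copies_of("s0", "A") == 2
        assert ok / reps >= 0.95


class TestHWE:
    def oracle(self, n_hom_ref, n_het, n_hom_alt):
        """Enumeration oracle in plain probability space."""
        n = n_hom_ref + n_het + n_hom_alt
        na = n_het + 2 * n_hom_alt
        rare = min(na, 2 * n - na)
        probs = {}
        for h in range(rare % 2, rare + 1, 2):
            hom_rare = (rare - h) // 2
            hom_common = n - h - hom_rare
            probs[h] = (math.comb(n, hom_rare) * math.comb(n - hom_rare, h)
                        * 2 ** h) / 1.0
            # conditional distribution normalised below
        z = sum(probs.values())
        probs = {h: p / z for h, p in probs.items()}
        obs = probs[n_het]
        return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))

    @pytest.mark.parametrize("counts", [
        (81, 18, 1), (90, 0, 10), (25, 50, 25), (97, 3, 0), (5, 5, 5),
    ])
    def test_matches_enumeration_oracle(self, counts):
        assert al.hwe_exact_test(*counts) == pytest.approx(self.oracle(*counts))

    def test_equilibrium_passes_extreme_deficit_fails(self):
        assert al.hwe_exact_test(81, 18, 1) > 0.05
        assert al.hwe_exact_test(90, 0, 10) < 1e-6

    def test_monomorphic_is_trivially_consistent(self):
        assert al.hwe_exact_test(100, 0, 0) == 1.0


class TestGenotypeAndFilter:
    def manifest(self, n=100, pop="A"):
        return pd.DataFrame({"sample_id": [f"{pop}{i}" for i in range(n)],
                             "population": pop})

    def table(self, copies, allele="A"):
        rows = [{"sample_id": s, "allele_id": allele, "raw": float(c),
                 "copies": c, "flags": ""} for s, c in copies.items()]
        return al.AlleleCopyNumberTable(pd.DataFrame(rows))

    def test_copy_above_two_excluded(self):
        man = self.manifest(10)
        t = self.table({"A0": 3, "A1": 1})
        rep = al.genotype_and_filter(t, man)
        assert rep.excluded == {"A": al.CN_GT2}

    def test_pure_triplication_genotyped_heterozygous(self):
        man = self.manifest(20)
        t = self.table({f"A{i}": 2 for i in range(4)})
        rep = al.genotype_and_filter(t, man)
        assert "A" in rep.triplications
        g = rep.genotypes.set_index("sample_id")["genotype"]
        assert (g.loc[[f"A{i}" for i in range(4)]] == 1).all()
        assert g.loc["A10"] == 0

    def test_hwe_violation_excluded(self):
        man = self.manifest(100)
        # 10 homozygotes, no heterozygotes: flagrant HWE violation
        t = self.table({f"A{i}": 2 for i in range(10)})
        t.table.loc[0, "copies"] = 1  # not a pure triplication
        rep = al.genotype_and_filter(t, man)
        assert rep.excluded == {"A": al.HWE_FAIL}

    def test_equilibrium_allele_retained(self):
        man = self.manifest(100)
        copies = {f"A{i}": 1 for i in range(18)}
        copies["A99"] = 2
        rep = al.genotype_and_filter(self.table(copies), man)
        assert rep.excluded == {}
        assert len(rep.genotypes) == 100

    def test_sample_order_invariance(self):
        man = self.manifest(50)
        copies = {f"A{i}": (3 if i == 7 else 1) for i in range(10)}
        rep1 = al.genotype_and_filter(self.table(copies), man)
        shuffled = dict(reversed(list(copies.items())))
        rep2 = al.genotype_and_filter(self.table(shuffled), man)
        assert rep1.excluded == rep2.excluded

    def test_hwe_filter_passes_equilibrium_cohorts(self):
        """Planted duplication at HWE should rarely be filtered out."""
        rng = np.random.default_rng(8)
        man = self.manifest(100)
        passed = 0
        reps = 100
        for _ in range(reps):
            g = rng.binomial(2, 0.2, 100)  # genotypes under HWE, p=0.2
            copies = {f"A{i}": int(c) for i, c in enumerate(g)}
            if any(c > 0 for c in copies.values()) \
                    and not all(c == 2 for c in copies.values() if c > 0):
                rep = al.genotype_and_filter(self.table(copies), man)
                passed += "A" not in rep.excluded
            else:
                passed += 1
        assert passed / reps >= 0.90


class TestClipConsensus:
    def test_identical_clips(self):
        clips = [al.SoftClipRecord("s0", "2R", 100, "ACGTACGT", "end")] * 3
        assert al.clip_consensus(clips) == "ACGTACGT"

    def test_majority_wins_single_mismatch(self):
        seqs = ["ACGT", "ACGT", "ACTT"]
        clips = [al.SoftClipRecord("s0", "2R", 100, s, "end") for s in seqs]
        assert al.clip_consensus(clips) == "ACGT"

    def test_start_side_right_justified(self):
        seqs = ["CGT", "ACGT", "ACGT"]
        clips = [al.SoftClipRecord("s0", "2R", 100, s, "start") for s in seqs]
        assert al.clip_consensus(clips) == "ACGT"

    def test_simulator_roundtrip_and_fasta_export(self, tmp_path):
        ref = sim.make_reference(1, (("2R", 120_000),))
        cnv = sim.PlantedCNV("s0", "2R", 100, 120, allele_id="DupZ")
        _, clips = sim.simulate_breakpoint_reads(ref, [cnv], INSERT, seed=4)
        sigs = sim.signatures_for_planted(ref, [cnv])
        out = tmp_path / "clips.fasta"
        n = al.breakpoint_clip_export(sigs, clips, str(out))
        assert n == 2
        text = out.read_text().splitlines()
        assert text[0] == ">DupZ/start"
        assert text[1] == sigs[0].clip_consensus  # planted truth sequence
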