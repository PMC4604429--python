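"""Multi-mapper-aware TE quantification, strand bias, condition comparison."""

import math

import numpy as np
import pytest

from pirnaflow.te_quant import (
    compare_conditions,
    decreased_features,
    qualify_pirna_transcripts,
    quantify_te,
    strand_bias_table,
)

from conftest import lib_of, rec, uniq_seq


def te_lib(records, lengths):
    return lib_of(records, ref_lengths=lengths)


class TestQuantifyTE:
    def test_multiplicity_division(self):
        seq = uniq_seq(30)
        recs = [rec("TE_A", 10, 30, "+", seq=seq, copy=4),
                rec("TE_B", 10, 30, "+", seq=seq, copy=4)]
        lib = te_lib(recs, {"TE_A": 2000, "TE_B": 2000})
        quants = {q.te_id: q for q in quantify_te(lib, 1_000_000)}
        assert quants["TE_A"].weighted_count == pytest.approx(2.0)
        assert quants["TE_B"].weighted_count == pytest.approx(2.0)

    def test_norm_expr_arithmetic(self):
        # 2-kb consensus, weighted count 100, 1e6 genome-mapped -> 50
        recs = [rec("TE_A", 40 * i, 30, "+", copy=1) for i in range(100)]
        lib = te_lib(recs, {"TE_A": 2000})
        (q,) = quantify_te(lib, 1_000_000)
        assert q.weighted_count == pytest.approx(100.0)
        assert q.norm_expr == pytest.approx(50.0)

    def test_zero_placement_te_reported_with_zeros(self):
        lib = te_lib([rec("TE_A", 0, 30, "+")], {"TE_A": 1000, "TE_B": 1000})
        quants = {q.te_id: q for q in quantify_te(lib, 1000)}
        assert quants["TE_B"].weighted_count == 0.0
        assert quants["TE_B"].norm_expr == 0.0

    def test_zero_length_consensus_rejected(self):
        lib = te_lib([], {"TE_A": 0})
        with pytest.raises(ValueError):
            quantify_te(lib, 1000)

    def test_conservation_and_brute_force_oracle(self, default_sim,
                                                 default_genome_lib):
        lib = default_sim.te_library("luciferase", 1,
                                    default_genome_lib.total_mapped)
        quants = quantify_te(lib, default_genome_lib.total_mapped)
        total_weighted = sum(q.weighted_count for q in quants)
        aligned = sum(r.copy_count for r in lib.distinct_reads())
        assert total_weighted == pytest.approx(aligned, rel=1e-12)
        # oracle: per-read loop
        expected = {}
        for r in lib.records:
            expected[r.ref_id] = expected.get(r.ref_id, 0.0) + (
                r.read.copy_count / r.n_hits)
        for q in quants:
            assert q.weighted_count == pytest.approx(
                expected.get(q.te_id, 0.0), rel=1e-12)

    def test_planted_expression_recovered(self, default_sim,
                                          default_genome_lib):
        lib = default_sim.te_library("luciferase", 1,
                                    default_genome_lib.total_mapped)
        quants = quantify_te(lib, default_genome_lib.total_mapped)
        e = default_sim.truth.te_expression
        r = np.corrcoef([q.norm_expr for q in quants],
                        [e[q.te_id] for q in quants])[0, 1]
        assert r > 0.95


class TestStrandBias:
    def test_all_antisense_and_balanced(self):
        anti = te_lib([rec("TE_A", 30 + 10 * i, 30, "-", copy=1)
                       for i in range(1, 21)], {"TE_A": 1000})
        anti.name = "libA"
        bal = te_lib(
            [rec("TE_A", 30 + 10 * i, 30, "+-"[i % 2], copy=1)
             for i in range(1, 21)], {"TE_A": 1000})
        bal.name = "libB"
        df = strand_bias_table([anti, bal], {"libA": 1000, "libB": 1000})
        assert df.loc["TE_A", "libA"] == 0.0
        assert df.loc["TE_A", "libB"] == 0.5

    def test_low_count_masked_and_masking_monotone(self):
        lib = te_lib([rec("TE_A", 10 * i, 30, "+", copy=1)
                      for i in range(1, 6)], {"TE_A": 1000, "TE_B": 1000})
        lib.name = "lib"
        df10 = strand_bias_table([lib], {"lib": 1000}, min_count=10)
        df1 = strand_bias_table([lib], {"lib": 1000}, min_count=1)
        assert math.isnan(df10.loc["TE_A", "lib"])
        assert df1.loc["TE_A", "lib"] == 1.0
        assert df1.notna().values.sum() >= df10.notna().values.sum()

    def test_planted_sense_fraction_recovered(self):
        rng = np.random.default_rng(0)
        recs = [rec("TE_A", int(rng.integers(30, 960)), 30,
                    "+" if rng.random() < 0.9 else "-", copy=1)
                for _ in range(10_000)]
        lib = te_lib(recs, {"TE_A": 1000})
        lib.name = "lib"
        df = strand_bias_table([lib], {"lib": 10_000})
        assert df.loc["TE_A", "lib"] == pytest.approx(0.9, abs=0.02)


class TestTranscriptQualification:
    def test_rpkm_rule(self):
        recs = [rec("t1", 4 * i, 30, "+", copy=1) for i in range(60)]
        lib = te_lib(recs, {"t1": 500})
        (q,) = qualify_pirna_transcripts(lib, 1_000_000)
        assert q.rpkm == pytest.approx(120.0)
        assert q.rpm == pytest.approx(60.0)
        assert q.qualifies

    def test_boundary_not_qualified(self):
        # 99.9 RPKM and 99.9 RPM both under the threshold
        recs = [rec("t1", i, 30, "+", copy=1) for i in range(200)]
        lib = te_lib(recs, {"t1": 1000})
        total = int(round(200 / 99.9 * 1e6 / 1000) * 1000)
        (q,) = qualify_pirna_transcripts(lib, total)
        assert q.rpkm < 100 and q.rpm < 100 and not q.qualifies

    def test_or_rule_rpm_alone_qualifies(self):
        # long transcript: RPKM 75 but RPM 150 -> qualifies
        recs = [rec("t1", 10 * i, 30, "+", copy=1) for i in range(150)]
        lib = te_lib(recs, {"t1": 2000})
        (q,) = qualify_pirna_transcripts(lib, 1_000_000)
        assert q.rpkm == pytest.approx(75.0)
        assert q.rpm == pytest.approx(150.0)
        assert q.qualifies

    def test_only_pirna_sized_reads_counted(self):
        recs = [rec("t1", 4 * i, 30, "+", copy=1) for i in range(60)]
        recs += [rec("t1", 300 + 4 * i, 22, "+", copy=50) for i in range(20)]
        lib = te_lib(recs, {"t1": 500})
        (q,) = qualify_pirna_transcripts(lib, 1_000_000)
        assert q.raw_count == pytest.approx(60.0)


class TestCompareConditions:
    def counts(self, ctrl_mean, trt_mean, n=3, rng=None):
        out, design = {}, {}
        for i in range(n):
            out[f"c{i}"] = {"f": float(ctrl_mean)}
            design[f"c{i}"] = "control"
            out[f"t{i}"] = {"f": float(trt_mean)}
            design[f"t{i}"] = "treatment"
        return out, design

    def test_identical_arms_zero(self):
        counts, design = self.counts(100, 100)
        (c,) = compare_conditions(counts, design)
        assert c.log2fc == 0.0

    def test_absent_feature_pseudocount(self):
        counts, design = self.counts(100, 0)
        counts["t0"], counts["t1"], counts["t2"] = {}, {}, {}
        (c,) = compare_conditions(counts, design, epsilon=0.5)
        assert c.log2fc == pytest.approx(math.log2(0.5 / 100.5))

    def test_tenfold_depletion_recovered(self):
        rng = np.random.default_rng(3)
        counts, design = {}, {}
        for i in range(3):
            counts[f"c{i}"] = {f"f{j}": float(rng.poisson(1000))
                               for j in range(20)}
            design[f"c{i}"] = "control"
            counts[f"t{i}"] = {f"f{j}": float(rng.poisson(100))
                               for j in range(20)}
            design[f"t{i}"] = "treatment"
        comps = compare_conditions(counts, design)
        mean_fc = np.mean([c.log2fc for c in comps])
        assert mean_fc == pytest.approx(-math.log2(10), abs=0.1)
        assert set(decreased_features(comps)) == {c.feature_id for c in comps}

    def test_missing_arm_rejected(self):
        counts, design = self.counts(1, 1)
        design = {k: "control" for k in design}
        with pytest.raises(ValueError):
            compare_conditions(counts, design)
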