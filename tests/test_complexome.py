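"""Substoichiometry normalization, differential abundance and the
accumulation × synthesis group classification."""

import numpy as np
import pandas as pd
import pytest

from fracsynth import complexome as cx


def lfq_frame(data, samples):
    return pd.DataFrame(data, columns=samples, dtype=float)


class TestSubstoichiometry:
    SAMPLES = ["s1", "s2"]

    def test_within_class_values_sum_to_one(self):
        lfq = pd.DataFrame({"s1": [2.0, 6.0, 2.0], "s2": [1.0, 1.0, 2.0]},
                           index=["L1", "L2", "L3"])
        classes = {p: "60S" for p in lfq.index}
        out = cx.substoichiometry(lfq, classes)
        assert np.allclose(out["s1"], [0.2, 0.6, 0.2])
        assert np.allclose(out.sum(axis=0), 1.0)

    def test_single_member_class_is_always_one(self):
        lfq = pd.DataFrame({"s1": [5.0], "s2": [0.1]}, index=["P1"])
        out = cx.substoichiometry(lfq, {"P1": "40S"})
        assert (out.loc["P1"] == 1.0).all()

    def test_missing_protein_excluded_from_sample_sum(self):
        lfq = pd.DataFrame({"s1": [2.0, 2.0], "s2": [np.nan, 2.0]},
                           index=["A", "B"])
        out = cx.substoichiometry(lfq, {"A": "60S", "B": "60S"})
        assert out.loc["A", "s1"] == pytest.approx(0.5)
        assert np.isnan(out.loc["A", "s2"])
        assert out.loc["B", "s2"] == pytest.approx(1.0)

    def test_unmapped_proteins_stay_missing(self):
        lfq = pd.DataFrame({"s1": [1.0, 1.0]}, index=["A", "X"])
        out = cx.substoichiometry(lfq, {"A": "40S"})
        assert np.isnan(out.loc["X", "s1"])

    def test_negative_intensity_rejected(self):
        lfq = pd.DataFrame({"s1": [-1.0]}, index=["A"])
        with pytest.raises(ValueError):
            cx.substoichiometry(lfq, {"A": "40S"})


def two_condition_lfq(n_proteins, fold_changes, rng, cv=0.1, n_rep=3):
    samples, conds = [], {}
    for cond in ("cold", "control"):
        for r in range(1, n_rep + 1):
            name = f"{cond}_{r}"
            samples.append(name)
            conds[name] = cond
    data = {}
    for i in range(n_proteins):
        base = 1e8
        fc = fold_changes.get(f"P{i}", 1.0)
        row = [base * (fc if conds[s] == "cold" else 1.0)
               * (1 + cv * rng.standard_normal()) for s in samples]
        data[f"P{i}"] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=samples), conds


class TestDifferentialAbundance:
    def test_two_fold_shift_detected(self, rng):
        detected = 0
        for _ in range(30):
            lfq, conds = two_condition_lfq(5, {"P0": 2.0}, rng)
            out = cx.differential_abundance(lfq, conds, ("cold", "control"))
            if out.loc["P0", "q"] < 0.1 and out.loc["P0", "log2fc"] > 0:
                detected += 1
        assert detected / 30 > 0.8  # power at n=3, CV 10%

    def test_null_type_one_error_controlled(self, rng):
        lfq, conds = two_condition_lfq(800, {}, rng)
        out = cx.differential_abundance(lfq, conds, ("cold", "control"))
        rate = float((out["p"] < 0.05).mean())
        assert 0.01 < rate < 0.09  # ~5% raw false positives

    def test_insufficient_replicates_skipped(self, rng):
        lfq, conds = two_condition_lfq(3, {}, rng)
        lfq.loc["P0", [s for s in lfq.columns if "cold" in s][:2]] = np.nan
        out = cx.differential_abundance(lfq, conds, ("cold", "control"))
        assert out.loc["P0", "skip_reason"] == "insufficient_values"


class TestClassifyGroup:
    @pytest.mark.parametrize("acc,syn,group", [
        (True, True, 1), (True, False, 2), (False, True, 3), (False, False, 4),
    ])
    def test_truth_table(self, acc, syn, group):
        assert cx.classify_group(acc, syn) == group

    def test_undefined_flag_gives_undefined_group(self):
        assert cx.classify_group(None, True) is None

    def test_total_on_flag_square(self):
        groups = {cx.classify_group(a, s) for a in (True, False)
                  for s in (True, False)}
        assert groups == {1, 2, 3, 4}


class TestClassifyComplex:
    CONDITIONS = ("cold", "control")

    def diff_table(self, members, up_in_cold, q=0.001):
        rows = []
        for m in members:
            if m in up_in_cold:
                rows.append({"protein": m, "log2fc": 1.5, "p": q, "q": q,
                             "star": "***", "skip_reason": ""})
            else:
                rows.append({"protein": m, "log2fc": 0.0, "p": 0.9, "q": 0.95,
                             "star": "", "skip_reason": ""})
        return pd.DataFrame(rows).set_index("protein")

    def test_accumulated_and_synthesized_in_cold(self):
        members = ("A", "B", "C")
        cdef = cx.ComplexDefinition("ribosome", "GO:0022625", members)
        diff = self.diff_table(members, up_in_cold=members)
        syn = {(m, "cold"): True for m in members}
        cold = cx.classify_complex(cdef, diff, syn, "cold", self.CONDITIONS)
        ctrl = cx.classify_complex(cdef, diff, syn, "control", self.CONDITIONS)
        assert cold.group == 1
        assert ctrl.group == 4  # symmetric input: nothing in control

    def test_accumulated_without_synthesis_is_group_two(self):
        members = ("A", "B")
        cdef = cx.ComplexDefinition("pre-ribosome", "GO:0030687", members)
        diff = self.diff_table(members, up_in_cold=members)
        call = cx.classify_complex(cdef, diff, {}, "cold", self.CONDITIONS)
        assert call.group == 2

    def test_flat_but_labelled_everywhere_is_group_three(self):
        members = ("A", "B")
        cdef = cx.ComplexDefinition("eIF2", "GO:0005850", members)
        diff = self.diff_table(members, up_in_cold=())
        syn = {(m, c): True for m in members for c in self.CONDITIONS}
        for cond in self.CONDITIONS:
            assert cx.classify_complex(cdef, diff, syn, cond,
                                       self.CONDITIONS).group == 3

    def test_accumulation_is_antisymmetric_between_conditions(self):
        members = ("A", "B", "C")
        cdef = cx.ComplexDefinition("any", "GO:0000001", members)
        diff = self.diff_table(members, up_in_cold=("A", "B"))
        cold = cx.classify_complex(cdef, diff, {}, "cold", self.CONDITIONS)
        ctrl = cx.classify_complex(cdef, diff, {}, "control", self.CONDITIONS)
        assert not (cold.accumulated and ctrl.accumulated)

    def test_undetected_complex(self):
        cdef = cx.ComplexDefinition("ghost", "GO:0009999", ("ZZ",))
        diff = self.diff_table(("A",), up_in_cold=())
        call = cx.classify_complex(cdef, diff, {}, "cold", self.CONDITIONS)
        assert call.group is None and "not_detected" in call.flags

    def test_member_subsets_reported(self):
        members = ("A", "B", "C", "D", "E")
        cdef = cx.ComplexDefinition("mixed", "GO:0000002", members)
        diff = self.diff_table(members, up_in_cold=("A",))
        call = cx.classify_complex(cdef, diff, {}, "cold", self.CONDITIONS)
        assert call.accumulated_members == ("A",)
        assert call.accumulated is False  # minority subset, majority rule

    def test_invalid_go_id_rejected(self):
        with pytest.raises(ValueError, match="GO"):
            cx.ComplexDefinition("bad", "GO:123", ("A",))


class TestSubunitRatio:
    def test_exact_three_to_one(self):
        lfq = pd.DataFrame({
            "s1": [3.0, 3.0, 1.0, 1.0],
            "s2": [6.0, 6.0, 2.0, 2.0],
            "s3": [1.5, 1.5, 0.5, 0.5],
        }, index=["L1", "L2", "S1", "S2"])
        classes = {"L1": "60S", "L2": "60S", "S1": "40S", "S2": "40S"}
        ratio, r2 = cx.subunit_ratio(lfq, classes)
        assert np.allclose(ratio, 3.0)
        assert r2 == pytest.approx(1.0)

    def test_ratio_invariant_to_sample_scaling(self):
        lfq = pd.DataFrame({"s1": [3.0, 1.0], "s2": [30.0, 10.0]},
                           index=["L", "S"])
        classes = {"L": "60S", "S": "40S"}
        ratio, _ = cx.subunit_ratio(lfq, classes)
        assert ratio["s1"] == pytest.approx(ratio["s2"])

    def test_noisy_proportional_sums_correlate(self, rng):
        ssu = rng.uniform(0.5, 2.0, size=12)
        data = {}
        for i, s in enumerate(ssu):
            noise = 1 + 0.05 * rng.standard_normal(2)
            data[f"s{i}"] = [3 * s * noise[0], s * noise[1]]
        lfq = pd.DataFrame(data, index=["L", "S"])
        _, r2 = cx.subunit_ratio(lfq, {"L": "60S", "S": "40S"})
        assert r2 > 0.95
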