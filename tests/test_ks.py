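"""Significance filtering, pool-dilution correction and synthesis rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fracsynth import ks
from fracsynth.pools import AAEnrichmentTable
from fracsynth.stats import bh_adjust


def enrichment_rows(analyte, condition, labelled_vals, unlabelled_vals,
                    residual=0.0, completeness=1.0):
    rows = []
    for i, v in enumerate(labelled_vals):
        rows.append({"analyte_id": analyte, "condition": condition,
                     "replicate": i + 1, "labelled": True, "enrichment": v,
                     "residual": residual, "completeness": completeness})
    for i, v in enumerate(unlabelled_vals):
        rows.append({"analyte_id": analyte, "condition": condition,
                     "replicate": i + 1, "labelled": False, "enrichment": v,
                     "residual": residual, "completeness": completeness})
    return rows


class TestLPFFilter:
    def test_clearly_labelled_peptide_passes(self):
        df = pd.DataFrame(enrichment_rows(
            "PEP1/2", "cold", [0.10, 0.11, 0.09], [0.000, 0.001, -0.001]))
        out = ks.lpf_filter(df)
        assert bool(out["pass_filter"].iloc[0])
        assert out["q"].iloc[0] < 0.05

    def test_unlabelled_peptide_fails(self):
        df = pd.DataFrame(enrichment_rows(
            "PEP1/2", "cold", [0.0005, -0.0003, 0.0002], [0.0, 0.0004, -0.0002]))
        out = ks.lpf_filter(df)
        assert not bool(out["pass_filter"].iloc[0])

    def test_single_replicate_fails_with_reason(self):
        df = pd.DataFrame(enrichment_rows("PEP1/2", "cold", [0.10], []))
        out = ks.lpf_filter(df)
        assert not bool(out["pass_filter"].iloc[0])
        assert "insufficient_replicates" in out["fail_reason"].iloc[0]

    def test_quality_gates_engage(self):
        bad_res = pd.DataFrame(enrichment_rows(
            "A/2", "cold", [0.1, 0.11, 0.09], [0.0, 0.0], residual=0.5))
        incomplete = pd.DataFrame(enrichment_rows(
            "B/2", "cold", [0.1, 0.11, 0.09], [0.0, 0.0], completeness=0.5))
        out = ks.lpf_filter(pd.concat([bad_res, incomplete]))
        reasons = dict(zip(out["analyte_id"], out["fail_reason"]))
        assert "high_residual" in reasons["A/2"]
        assert "incomplete_envelope" in reasons["B/2"]

    def test_funnel_counts_are_monotone(self):
        df = pd.DataFrame(
            enrichment_rows("A/2", "cold", [0.1, 0.11, 0.09], [0.0, 0.0])
            + enrichment_rows("B/2", "cold", [0.1], [])
            + enrichment_rows("C/2", "cold", [0.001, -0.001, 0.0], [0.0, 0.0])
        )
        funnel = ks.filter_funnel(ks.lpf_filter(df))
        counts = funnel["n_remaining"].tolist()
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 3 and counts[-1] == 1


class TestMaxLPF:
    @pytest.mark.parametrize(
        "seq,pools,expected",
        [
            ("GS", {"G": 0.15, "S": 0.15}, 0.15),
            ("GK", {"G": 0.15}, 0.15),  # lysine excluded: e_K = 0
            ("GS", {"G": 0.10, "S": 0.20}, 0.15),
        ],
    )
    def test_values(self, seq, pools, expected):
        assert ks.max_lpf(seq, pools) == pytest.approx(expected)

    def test_no_labelable_atoms_is_nan(self):
        assert np.isnan(ks.max_lpf("AA", {}))

    def test_nitrogen_weighting(self):
        # Q carries 2 N, G carries 1: E_max = (2*0.06 + 1*0.15) / 3
        assert ks.max_lpf("QG", {"Q": 0.06, "G": 0.15}) == \
            pytest.approx((2 * 0.06 + 0.15) / 3)


class TestCorrectedLPFAndKs:
    def test_ratio(self):
        value, flags = ks.corrected_lpf(0.03, 0.15)
        assert value == pytest.approx(0.20) and flags == []

    def test_zero_lpf(self):
        assert ks.corrected_lpf(0.0, 0.15)[0] == 0.0

    def test_above_one_flagged_not_truncated(self):
        value, flags = ks.corrected_lpf(0.18, 0.15)
        assert value == pytest.approx(1.2)
        assert "pool_underestimate" in flags

    def test_nonpositive_emax_rejected(self):
        with pytest.raises(ValueError):
            ks.corrected_lpf(0.1, 0.0)

    def test_ks_rate_arithmetic_and_linearity(self):
        assert ks.ks_rate(0.20, 0.017) == pytest.approx(0.34)
        assert ks.ks_rate(0.0, 0.017) == 0.0
        assert ks.ks_rate(0.3, 0.034) == pytest.approx(2 * ks.ks_rate(0.3, 0.017))


def peptide_frame(rows):
    return pd.DataFrame(rows, columns=[
        "analyte_id", "sequence", "condition", "lpf", "e_max",
        "corrected_lpf", "ks", "q", "pass_filter", "n_labelled", "flags"])


class TestAggregateProtein:
    def rows(self, ks_values, passing=True, analyte_prefix="PEP"):
        return [
            (f"{analyte_prefix}{i}/2", "GSK", "cold", 0.03, 0.15, v / 1.7, v,
             0.001, passing, 3, "")
            for i, v in enumerate(ks_values)
        ]

    def test_median_over_passing_peptides(self):
        df = peptide_frame(self.rows([0.3, 0.34, 0.4]))
        mapping = {f"PEP{i}/2": ("PROT1",) for i in range(3)}
        out = ks.aggregate_protein(df, mapping)
        assert out["median_ks"].iloc[0] == pytest.approx(0.34)
        assert bool(out["synthesized"].iloc[0])

    def test_no_passing_peptides_flagged_not_synthesized(self):
        df = peptide_frame(self.rows([0.3, 0.4], passing=False))
        mapping = {"PEP0/2": ("P1",), "PEP1/2": ("P1",)}
        out = ks.aggregate_protein(df, mapping)
        assert not bool(out["synthesized"].iloc[0])
        assert np.isnan(out["median_ks"].iloc[0])

    def test_shared_peptides_discarded(self):
        df = peptide_frame(self.rows([0.3]))
        mapping = {"PEP0/2": ("P1", "P2")}
        out = ks.aggregate_protein(df, mapping)
        assert out.empty


class TestCompareKs:
    def replicate_frame(self, means, cv=0.05, n=3, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for protein, by_cond in means.items():
            for cond, mu in by_cond.items():
                for rep in range(1, n + 1):
                    rows.append({
                        "protein": protein, "condition": cond, "replicate": rep,
                        "corrected_lpf": mu * (1 + cv * rng.standard_normal()),
                        "n_peptides": 5,
                    })
        return pd.DataFrame(rows)

    def test_strong_difference_gets_three_stars(self):
        df = self.replicate_frame({"P1": {"cold": 0.4, "control": 0.05}})
        out = ks.compare_ks(df, ("cold", "control"))
        assert out["q"].iloc[0] < 0.01
        assert out["star"].iloc[0] == "***"

    def test_missing_condition_skipped(self):
        df = self.replicate_frame({"P1": {"cold": 0.4}})
        out = ks.compare_ks(df, ("cold", "control"))
        assert out["skip_reason"].iloc[0] != ""
        assert np.isnan(out["p"].iloc[0])


class TestBHAdjustment:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=40))
    def test_q_values_monotone_in_p(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_nan_passthrough(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])
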