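"""Pattern derivation, dropout summaries and the Monte-Carlo exact test."""

import itertools
import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import comb

import patternmix as pm
from patternmix.data import PatternCrosstab, _log_table_prob


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

class TestReadLongCsv:
    def test_toy_csv(self, tmp_path):
        p = tmp_path / "toy.csv"
        p.write_text("id,week,y,drug\nA,0,5.0,1\nA,1,4.5,1\nA,3,4.0,1\n")
        ds = pm.read_long_csv(p)
        assert ds.n_subjects == 1
        assert len(ds.records) == 3
        assert ds.covariates.loc["A", "drug"] == 1

    def test_missing_response_rows_dropped(self, tmp_path):
        p = tmp_path / "na.csv"
        p.write_text("id,week,y,drug\nA,0,5.0,1\nA,1,,1\nA,3,4.0,1\n")
        ds = pm.read_long_csv(p)
        assert sorted(ds.records["week"]) == [0, 3]

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("id,week,y\n")
        ds = pm.read_long_csv(p)
        assert ds.n_subjects == 0 and len(ds.records) == 0

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,week\nA,0\n")
        with pytest.raises(pm.ConfigurationError, match="'y'"):
            pm.read_long_csv(p)

    def test_duplicate_rows_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("id,week,y\nA,0,5.0\nA,0,4.0\n")
        with pytest.raises(pm.DataError, match="duplicate"):
            pm.read_long_csv(p)

    def test_time_varying_covariate_rejected(self, tmp_path):
        p = tmp_path / "tv.csv"
        p.write_text("id,week,y,drug\nA,0,5.0,1\nA,1,4.0,0\n")
        with pytest.raises(pm.DataError, match="drug"):
            pm.read_long_csv(p)

    def test_round_trip(self, tmp_path):
        ds = pm.generate_empirical_like(60, seed=3)
        p = tmp_path / "rt.csv"
        ds.to_csv(p)
        back = pm.read_long_csv(p)
        a = ds.records.sort_values(["subject", "week"]).reset_index(drop=True)
        b = back.records.sort_values(["subject", "week"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)
        pd.testing.assert_frame_equal(
            ds.covariates.sort_index(), back.covariates.sort_index(),
            check_dtype=False,
        )


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

def _oracle_class(mask: str) -> str:
    """Independent statement of the classification rule by enumeration of
    structure: complete / prefix-of-ones / trailing-observed / otherwise."""
    if mask == "1" * len(mask):
        return "complete"
    # monotone: some a >= 0 ones then only zeros
    for a in range(len(mask)):
        if mask == "1" * a + "0" * (len(mask) - a):
            return "monotone_dropout"
    return "intermittent" if mask.endswith("1") else "mixed"


@pytest.mark.parametrize(
    "mask", ["".join(bits) for bits in itertools.product("01", repeat=4)]
)
def test_classify_mask_all_16(mask):
    assert pm.classify_mask(mask) == _oracle_class(mask)


@given(st.lists(st.sampled_from("01"), min_size=1, max_size=8).map("".join))
def test_classify_mask_property(mask):
    assert pm.classify_mask(mask) == _oracle_class(mask)


class TestClassifyPatterns:
    def test_reference_frequencies(self, empirical_patterns):
        freq = empirical_patterns.frequencies
        assert freq[1] == 312
        assert freq.sum() == 437
        assert list(freq) == [312, 53, 45, 13, 5, 3, 3, 2, 1]
        assert empirical_patterns.mask_of_pattern[1] == "1111"

    def test_single_complete_subject(self, toy_dataset_factory):
        ds = toy_dataset_factory([("1111", 0), ("1110", 1)])
        pa = pm.classify_patterns(ds)
        assert pa.masks.iloc[0] == "1111"
        assert pa.pattern_class.iloc[0] == "complete"

    def test_mask_matches_record_presence(self, empirical_ds, empirical_patterns):
        present = set(zip(empirical_ds.records["subject"], empirical_ds.records["week"]))
        for s, mask in empirical_patterns.masks.items():
            for w, bit in zip(empirical_ds.key_weeks, mask):
                assert ((s, w) in present) == (bit == "1")

    def test_zero_observed_key_weeks_warns(self, caplog):
        rec = pd.DataFrame({"subject": ["A", "B"], "week": [2, 0], "y": [3.0, 4.0]})
        cov = pd.DataFrame(index=pd.Index(["A", "B"], name="subject"))
        ds = pm.LongitudinalDataset(rec, cov)
        with caplog.at_level(logging.WARNING, logger="patternmix"):
            pa = pm.classify_patterns(ds)
        assert pa.masks["A"] == "0000"
        assert "no key week" in caplog.text


# ---------------------------------------------------------------------------
# dropout summary
# ---------------------------------------------------------------------------

class TestDropoutSummary:
    def test_reference_counts(self, empirical_dropout):
        assert int(empirical_dropout.drop.sum()) == 102
        assert empirical_dropout.drop_proportion == pytest.approx(0.2334, abs=5e-5)

    def test_drop_iff_final_key_week_missing(self, empirical_patterns, empirical_dropout):
        expect = empirical_patterns.masks.str[-1].eq("0").astype(int)
        pd.testing.assert_series_equal(
            empirical_dropout.drop, expect, check_names=False
        )

    def test_baseline_only_subject_finite(self, toy_dataset_factory):
        ds = toy_dataset_factory([("1000", 0), ("1111", 1), ("1110", 0)])
        pa = pm.classify_patterns(ds)
        d = pm.dropout_summary(ds, pa)
        assert d.max_week.iloc[0] == 0
        assert d.ln_max_week.iloc[0] == pytest.approx(math.log(1.0))
        assert np.isfinite(d.ln_max_week).all()

    def test_week_renumbering_reproduces_reference_regression(
        self, empirical_ds, empirical_dropout
    ):
        # group means of ln(last observed week + 1) are the closed-form
        # dropout-time regression coefficients
        g = empirical_ds.covariates["drug"]
        a0 = empirical_dropout.ln_max_week[g == 0].mean()
        a1 = empirical_dropout.ln_max_week[g == 1].mean() - a0
        assert a0 == pytest.approx(1.63, abs=0.005)
        assert a1 == pytest.approx(0.13, abs=0.005)


# ---------------------------------------------------------------------------
# crosstab and the exact test
# ---------------------------------------------------------------------------

class TestCrosstab:
    def test_reference_expected_count(self, empirical_patterns, empirical_ds):
        ct = pm.pattern_crosstab(empirical_patterns, empirical_ds.covariates["drug"])
        assert round(ct.expected.iloc[0, 0]) == 77
        assert ct.expected.to_numpy().sum() == pytest.approx(
            ct.observed.to_numpy().sum(), abs=1e-9
        )

    def test_uniform_table(self, toy_dataset_factory):
        ds = toy_dataset_factory([("1111", 0)] * 5 + [("1111", 1)] * 5
                                 + [("1110", 0)] * 5 + [("1110", 1)] * 5)
        ct = pm.pattern_crosstab(pm.classify_patterns(ds), ds.covariates["drug"])
        assert (ct.expected.to_numpy() == 5).all()

    def test_hand_arithmetic(self, toy_dataset_factory):
        # observed [[2, 8], [6, 4]] -> expected row1col1 = 10 * 8 / 20 = 4
        ds = toy_dataset_factory(
            [("1111", 0)] * 2 + [("1111", 1)] * 8
            + [("1110", 0)] * 6 + [("1110", 1)] * 4
        )
        ct = pm.pattern_crosstab(pm.classify_patterns(ds), ds.covariates["drug"])
        # frequency tie (10 vs 10) broken by ascending mask: '1110' first
        assert ct.observed.to_numpy().tolist() == [[6, 4], [2, 8]]
        assert ct.expected.iloc[1, 0] == pytest.approx(10 * 8 / 20)

    def test_single_level_group_warns(self, toy_dataset_factory, caplog):
        ds = toy_dataset_factory([("1111", 1), ("1110", 1)])
        with caplog.at_level(logging.WARNING, logger="patternmix"):
            ct = pm.pattern_crosstab(pm.classify_patterns(ds), ds.covariates["drug"])
        assert "single level" in caplog.text
        np.testing.assert_allclose(ct.expected, ct.observed)


def _crosstab_from_array(a):
    obs = pd.DataFrame(np.asarray(a))
    row, col = obs.sum(axis=1), obs.sum(axis=0)
    exp = pd.DataFrame(np.outer(row, col) / row.sum())
    return PatternCrosstab(observed=obs, expected=exp, row_totals=row, col_totals=col)


class TestMcExactTest:
    def test_2x2_against_enumeration(self):
        obs = [[3, 1], [1, 3]]
        ct = _crosstab_from_array(obs)
        # exhaustive enumeration over tables with margins (4,4)/(4,4)
        probs = {}
        for a in range(5):
            t = np.array([[a, 4 - a], [4 - a, a]])
            probs[a] = comb(4, a) * comb(4, 4 - a) / comb(8, 4)
        p_obs = probs[3]
        exact = sum(p for p in probs.values() if p <= p_obs + 1e-12)
        reps = 40_000
        p_mc = pm.mc_exact_independence_test(ct, reps=reps, seed=2)
        se = math.sqrt(exact * (1 - exact) / reps)
        assert abs(p_mc - exact) < 3 * se

    def test_proportional_table_p_one(self):
        ct = _crosstab_from_array([[10, 20], [5, 10], [15, 30]])
        p = pm.mc_exact_independence_test(ct, reps=2000, seed=0)
        assert p > 0.8

    def test_seed_reproducible(self):
        ct = _crosstab_from_array([[3, 1], [1, 3]])
        p1 = pm.mc_exact_independence_test(ct, reps=2000, seed=5)
        p2 = pm.mc_exact_independence_test(ct, reps=2000, seed=5)
        assert p1 == p2

    def test_degenerate_margin_rejected(self):
        ct = _crosstab_from_array([[0, 0], [3, 4]])
        with pytest.raises(pm.DataError, match="row"):
            pm.mc_exact_independence_test(ct, reps=2000, seed=0)

    def test_too_few_reps_rejected(self):
        ct = _crosstab_from_array([[3, 1], [1, 3]])
        with pytest.raises(pm.ConfigurationError):
            pm.mc_exact_independence_test(ct, reps=10, seed=0)


def test_write_pattern_table(tmp_path, empirical_ds, empirical_patterns):
    ct = pm.pattern_crosstab(empirical_patterns, empirical_ds.covariates["drug"])
    out = tmp_path / "patterns.csv"
    table = pm.write_pattern_table(empirical_ds, empirical_patterns, ct, out)
    assert out.exists()
    assert table.loc[1, "count"] == 312
    assert table.loc[1, "class"] == "complete"
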