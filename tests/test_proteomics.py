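"""Proteomics stage: cleaning, filtering, imputation, testing, tiering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirprot.containers import ConfigurationError
from mirprot.io import FormatError, read_protein_groups, write_protein_groups
from mirprot.proteomics import (ImputationParams, classify_targets,
                                compute_zscores, cv_summary,
                                filter_valid_values, impute_mnar,
                                load_and_clean, protein_table_to_matrix,
                                run_protein_de, welch_test)
from mirprot.synthetic import SimConfig, simulate_lfq

from conftest import make_matrix


class TestLoadAndClean:
    def test_flagged_rows_dropped(self, toy_protein_groups):
        table, log = load_and_clean(toy_protein_groups)
        assert log == {"n_input": 10, "n_reverse": 2, "n_contaminant": 1,
                       "n_site_only": 1, "n_retained": 6}
        assert len(table) == 6

    def test_unflagged_passthrough(self, tmp_path, toy_protein_groups):
        table, _ = load_and_clean(toy_protein_groups)
        clean_path = tmp_path / "clean.txt"
        write_protein_groups(table, clean_path)
        table2, log2 = load_and_clean(clean_path)
        assert log2["n_retained"] == log2["n_input"] == 6
        pd.testing.assert_frame_equal(table.reset_index(drop=True), table2)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        pd.DataFrame({"Protein IDs": ["P1"]}).to_csv(path, sep="\t",
                                                     index=False)
        with pytest.raises(FormatError, match="Gene names"):
            read_protein_groups(path)

    def test_writer_reader_roundtrip(self, tmp_path):
        cfg = SimConfig(n_features=40, mnar_censor_quantile=0.2, seed=8)
        matrix, _ = simulate_lfq(cfg)
        df = pd.DataFrame({
            "Protein IDs": matrix.data.index,
            "Gene names": [f"G{i}" for i in range(40)],
            "Reverse": "", "Potential contaminant": "",
            "Only identified by site": "",
        })
        for col in matrix.data.columns:
            df[f"LFQ intensity {col}"] = matrix.data[col].to_numpy()
        path = tmp_path / "pg.txt"
        write_protein_groups(df, path)
        back = read_protein_groups(path)
        lfq_cols = [c for c in back.columns if c.startswith("LFQ intensity")]
        np.testing.assert_array_equal(back[lfq_cols].to_numpy(),
                                      df[lfq_cols].to_numpy())


class TestFilterValidValues:
    def test_group_absent_protein_rule_dependence(self):
        row = [1e7] * 5 + [np.nan] * 5
        m = make_matrix([row])
        assert len(filter_valid_values(m, rule="any").data) == 1
        assert len(filter_valid_values(m, rule="both").data) == 0

    def test_two_of_five_dropped_everywhere(self):
        row = [1e7, 1e7, np.nan, np.nan, np.nan] * 2
        m = make_matrix([row])
        assert len(filter_valid_values(m, rule="any").data) == 0
        assert len(filter_valid_values(m, rule="both").data) == 0

    def test_matches_brute_force_recount(self):
        matrix, _ = simulate_lfq(SimConfig(n_features=300,
                                           mnar_censor_quantile=0.3, seed=9))
        kept = filter_valid_values(matrix, min_valid=3, rule="any")
        mask = matrix.data.notna()
        expect = [fid for fid in matrix.data.index
                  if max(mask.loc[fid, cols].sum()
                         for cols in matrix.groups.values()) >= 3]
        assert list(kept.data.index) == expect

    def test_min_valid_above_group_size(self):
        m = make_matrix([[1.0] * 10])
        with pytest.raises(ConfigurationError):
            filter_valid_values(m, min_valid=6)


class TestImputation:
    def test_complete_matrix_unchanged(self):
        m = make_matrix(np.random.default_rng(0).normal(25, 2, (20, 10)),
                        log2_scale=True)
        out = impute_mnar(m, ImputationParams(seed=0))
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_observed_cells_bit_identical(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(25, 2, (200, 10))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        m = make_matrix(vals, log2_scale=True)
        out = impute_mnar(m, ImputationParams(seed=2))
        obs = ~np.isnan(vals)
        np.testing.assert_array_equal(out.data.to_numpy()[obs], vals[obs])
        assert not out.data.isna().any().any()

    def test_imputed_moments(self):
        """10^4 imputed entries in one column match Normal(m-1.8s, (0.3s)^2)."""
        rng = np.random.default_rng(3)
        n_obs, n_miss = 10_000, 10_000
        col = np.concatenate([rng.normal(25, 2, n_obs),
                              np.full(n_miss, np.nan)])
        m = make_matrix(col.reshape(-1, 1).repeat(4, axis=1),
                        group_sizes=(2, 2), log2_scale=True)
        # use a single column to avoid cross-column seed coupling
        obs = col[:n_obs]
        mean_obs, sd_obs = obs.mean(), obs.std(ddof=1)
        out = impute_mnar(m, ImputationParams(width=0.3, downshift=1.8, seed=4))
        imput = out.data.iloc[n_obs:, 0].to_numpy()
        se_mean = 0.3 * sd_obs / math.sqrt(n_miss)
        assert abs(imput.mean() - (mean_obs - 1.8 * sd_obs)) < 3 * se_mean
        se_sd = 0.3 * sd_obs / math.sqrt(2 * n_miss)
        assert abs(imput.std(ddof=1) - 0.3 * sd_obs) < 3 * se_sd

    def test_zero_downshift_small_width_near_mean(self):
        col = np.array([20.0, 22.0, 24.0, 26.0, np.nan, np.nan])
        m = make_matrix(col.reshape(-1, 1).repeat(4, axis=1),
                        group_sizes=(2, 2), log2_scale=True)
        out = impute_mnar(m, ImputationParams(width=1e-9, downshift=0.0,
                                              seed=5))
        assert out.data.iloc[4, 0] == pytest.approx(23.0, abs=1e-6)

    def test_too_few_observed_values(self):
        col = np.array([20.0, np.nan, np.nan, np.nan])
        m = make_matrix(col.reshape(-1, 1).repeat(4, axis=1),
                        group_sizes=(2, 2), log2_scale=True)
        with pytest.raises(ConfigurationError):
            impute_mnar(m, ImputationParams())

    def test_raw_scale_rejected(self):
        m = make_matrix([[1e7] * 10])
        with pytest.raises(ConfigurationError):
            impute_mnar(m, ImputationParams())


def _welch_oracle(a, b):
    """Textbook Welch formulas, coded independently of scipy."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    from scipy.stats import t as tdist
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert t == 0.0 and p == 1.0

    def test_matches_formula_oracle(self):
        a = [10.1, 10.4, 9.9, 10.2, 10.0]
        b = [12.0, 12.3, 11.8, 12.1, 12.2]
        t, df, p = welch_test(a, b)
        to, dfo, po = _welch_oracle(a, b)
        assert t == pytest.approx(to, abs=1e-10)
        assert df == pytest.approx(dfo, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)

    def test_p_decreases_with_mean_shift(self):
        base = np.array([10.0, 10.5, 9.5, 10.2, 9.8])
        prev = 1.1
        for shift in (0.5, 1.0, 2.0, 4.0):
            _, _, p = welch_test(base, base + shift)
            assert p < prev
            prev = p

    def test_degenerate_zero_variance(self):
        t, _, p = welch_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        t, _, p = welch_test([2.0, 2.0], [3.0, 3.0])
        assert p == 0.0

    def test_too_small_group(self):
        with pytest.raises(ConfigurationError):
            welch_test([1.0], [1.0, 2.0])


class TestZscores:
    def test_already_standardized(self):
        np.testing.assert_allclose(compute_zscores([-1, 0, 1]), [-1, 0, 1])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(-10 ** 6, 10 ** 6).map(lambda i: i / 1000.0),
                    min_size=3, max_size=30, unique=True))
    def test_normalization_identity(self, xs):
        z = compute_zscores(xs)
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self):
        x = np.array([0.3, -1.2, 2.5, 0.0, 1.1])
        np.testing.assert_allclose(compute_zscores(x),
                                   compute_zscores(3.0 * x + 7.0), atol=1e-12)

    def test_zero_spread_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_zscores([1.0, 1.0, 1.0])


class TestClassify:
    def test_boundary_logic(self):
        df = pd.DataFrame({"p_raw": [0.04, 0.04, 0.04, 0.2],
                           "z": [1.5, 0.5, 1.5, 3.0],
                           "ratio": [3.0, 10.0, 5.0, 10.0]})
        tiers = classify_targets(df)["tier"].tolist()
        assert tiers == ["differential", "not_significant", "top",
                         "not_significant"]

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(-4, 4),
                              st.floats(0.01, 20)), min_size=1, max_size=50))
    def test_tier_chain(self, rows):
        df = pd.DataFrame(rows, columns=["p_raw", "z", "ratio"])
        out = classify_targets(df)
        sig = out["tier"] != "not_significant"
        diff = out["tier"].isin(["differential", "top"])
        top = out["tier"] == "top"
        assert (top <= diff).all() and (diff <= sig).all()
        # significant never exceeds the plain p-filter
        assert (sig <= (out["p_raw"] < 0.05)).all()


class TestCvSummary:
    def test_constant_matrix(self):
        m = make_matrix(np.full((5, 10), 3.0))
        out = cv_summary(m)
        assert (out["average_cv_pct"] == 0).all()

    def test_two_feature_hand_computation(self):
        vals = np.array([[10.0, 12.0, 14.0, 10.0, 12.0] * 2,
                         [100.0, 90.0, 110.0, 95.0, 105.0] * 2])
        m = make_matrix(vals)
        out = cv_summary(m)
        cv1 = np.std(vals[0, :5], ddof=1) / np.mean(vals[0, :5]) * 100
        cv2 = np.std(vals[1, :5], ddof=1) / np.mean(vals[1, :5]) * 100
        assert out.loc["UNT", "average_cv_pct"] == pytest.approx(
            (cv1 + cv2) / 2, abs=1e-12)
        assert out.loc["UNT", "median_cv_pct"] == pytest.approx(
            np.median([cv1, cv2]), abs=1e-12)

    def test_simulated_cv_recovered(self):
        """Average sample CV matches the generator's population CV after the
        small-sample bias of the sd estimator (c4 factor at n=5)."""
        from scipy.special import gamma
        matrix, _ = simulate_lfq(SimConfig(n_features=2000, cv=0.25,
                                           de_fraction=0.0, seed=10))
        out = cv_summary(matrix)
        n = 5
        c4 = math.sqrt(2 / (n - 1)) * gamma(n / 2) / gamma((n - 1) / 2)
        expected = 25.0 * c4  # ~23.5% measured from 5 replicates
        assert (out["average_cv_pct"] - expected).abs().max() < 1.0
        assert (out["average_cv_pct"] - 25.0).abs().max() < 3.0


def test_run_protein_de_sensitivity_and_tiers():
    """Pipeline recovers planted 4-fold changes with high sensitivity."""
    cfg = SimConfig(n_features=2000, cv=0.2, de_fraction=0.1,
                    log2fc_range=(2.0, 2.0), mnar_censor_quantile=0.075,
                    seed=11)
    matrix, truth = simulate_lfq(cfg)
    de = run_protein_de(matrix, "UNT", "FAC", ImputationParams(seed=12))
    merged = de.join(truth.set_index("feature_id"))
    flagged = merged["tier"].isin(["differential", "top"])
    sens = flagged[merged["is_changed"]].mean()
    assert sens >= 0.9
    # tier chain on a real run
    sig = merged["tier"] != "not_significant"
    assert ((merged["tier"] == "top") <= flagged).all()
    assert (flagged <= sig).all()
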