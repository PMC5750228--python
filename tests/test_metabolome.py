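"""Peak-area QC, filtering, normalization, ordination, killed controls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from crustlink import default_scenario, simulate_dataset
from crustlink.metabolome import (PeakAreaTable, cluster_metabolites,
                                  fold_range_filter, killed_control_test,
                                  pca_ordinate, qc_filter, row_normalize,
                                  verdict_flag)

from conftest import cell_frame, table_from_cells


class TestQcFilter:
    def test_all_pass_is_identity(self):
        t = table_from_cells(cell_frame({"m1": [1, 2, 3]}))
        out = qc_filter(t)
        pd.testing.assert_frame_equal(out.areas, t.areas)

    def test_flagged_samples_removed(self):
        cells = cell_frame({"m1": [1, 2, 3, 4, 5, 6]},
                           stages=("C", "D"), times=(1.0, 9.0, 18.0))
        bad = [f"active-D-9h-r{r}" for r in (1, 2, 3)]
        t = table_from_cells(cells, qc_fail=bad)
        out = qc_filter(t)
        assert set(bad) & set(out.areas.columns) == set()
        assert out.n_samples == t.n_samples - 3

    def test_empty_table_rejected(self):
        t = table_from_cells(cell_frame({"m1": [1, 2, 3]}))
        empty = PeakAreaTable(t.areas.iloc[:, :0], t.meta.iloc[:0])
        with pytest.raises(ValueError):
            qc_filter(empty)

    def test_all_samples_failing_rejected(self):
        t = table_from_cells(cell_frame({"m1": [1, 2, 3]}))
        t.meta["qc_pass"] = False
        with pytest.raises(ValueError, match="every sample"):
            qc_filter(t)


class TestFoldRangeFilter:
    @pytest.mark.parametrize(
        "cells,expect_retained",
        [
            ([5.0, 5.0, 5.0], False),      # ratio 1
            ([1.0, 2.1, 1.0], True),       # ratio 2.1
            ([np.nan, 4.0, 2.0], True),    # ratio over positive means = 2
        ],
    )
    def test_ratio_rule(self, cells, expect_retained):
        t = table_from_cells(cell_frame({"m": cells}))
        retained, _ = fold_range_filter(t)
        assert (["m"] == retained) is expect_retained

    def test_too_few_cells_unevaluable(self):
        t = table_from_cells(cell_frame({"m": [np.nan, np.nan, 3.0]}))
        retained, unevaluable = fold_range_filter(t)
        assert retained == [] and unevaluable == ["m"]

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        base = [1.0, 1.7, 2.4]
        t1 = table_from_cells(cell_frame({"m": base}))
        t2 = table_from_cells(cell_frame({"m": [v * c for v in base]}))
        assert fold_range_filter(t1)[0] == fold_range_filter(t2)[0]


class TestRowNormalize:
    def test_divides_by_row_maximum(self):
        cells = cell_frame({"m": [2.0, 4.0, 8.0]})
        out = row_normalize(cells)
        assert list(out.loc["m"]) == [0.25, 0.5, 1.0]

    def test_single_value_row(self):
        cells = cell_frame({"m": [7.0]}, times=(1.0,))
        assert row_normalize(cells).loc["m"].iloc[0] == 1.0

    def test_idempotent(self):
        cells = cell_frame({"m": [2.0, 3.0, 5.0], "n": [1.0, 9.0, 4.0]})
        once = row_normalize(cells)
        pd.testing.assert_frame_equal(row_normalize(once), once)

    def test_range_and_max_invariant(self, dataset):
        means = dataset.active.cell_means()
        out = row_normalize(means)
        assert ((out >= 0) & (out <= 1)).all().all()
        assert np.allclose(out.max(axis=1), 1.0)

    def test_all_missing_row_rejected(self):
        cells = cell_frame({"m": [np.nan, np.nan, np.nan]})
        with pytest.raises(ValueError):
            row_normalize(cells)


class TestClustering:
    def test_identical_profiles_share_a_label(self):
        cells = cell_frame({"a": [1, 2, 3], "b": [1, 2, 3],
                            "c": [3, 2, 1], "d": [9, 1, 9]})
        labels, _ = cluster_metabolites(row_normalize(cells), k=3)
        assert labels["a"] == labels["b"]

    def test_k_equal_rows_gives_singletons(self):
        cells = cell_frame({"a": [1, 2, 3], "b": [3, 2, 1], "c": [2, 9, 2]})
        labels, _ = cluster_metabolites(row_normalize(cells), k=3)
        assert labels.nunique() == 3

    def test_k_larger_than_rows_rejected(self):
        cells = cell_frame({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            cluster_metabolites(cells, k=2)

    def test_recovers_three_archetypes(self):
        """Early / mid / late peaked profiles, five of each, noise off,
        separate into exactly the generating groups."""
        times = (0.05, 9.0, 18.0, 42.0, 49.5)
        archetypes = {
            "early": [1.0, 0.6, 0.3, 0.1, 0.05],
            "mid": [0.1, 0.8, 1.0, 0.4, 0.2],
            "late": [0.05, 0.1, 0.3, 0.8, 1.0],
        }
        profiles = {}
        for name, shape in archetypes.items():
            for i in range(5):
                profiles[f"{name}{i}"] = [v * (1 + 0.01 * i) for v in shape]
        cells = cell_frame(profiles, times=times)
        labels, _ = cluster_metabolites(row_normalize(cells), k=3)
        for name in archetypes:
            members = labels[[f"{name}{i}" for i in range(5)]]
            assert members.nunique() == 1
        assert labels.nunique() == 3


class TestPca:
    def test_duplicate_samples_share_scores(self):
        cells = cell_frame({"m1": [1, 5, 1], "m2": [2, 2, 9]})
        t = table_from_cells(cells, n_rep=2)
        scores, _ = pca_ordinate(t)
        # replicates within a cell are exact duplicates
        a = scores.loc["active-A-1h-r1"]
        b = scores.loc["active-A-1h-r2"]
        assert np.allclose(a, b)

    def test_explained_variance_sorted_and_bounded(self, dataset):
        _, explained = pca_ordinate(dataset.active)
        assert (np.diff(explained) <= 1e-12).all()
        assert 0 < explained.sum() <= 1 + 1e-9

    def test_two_metabolite_closed_form(self):
        """PC1 fraction equals the larger eigenvalue of the hand-built
        2x2 covariance of the log-transformed data."""
        logvals = np.array([[0.0, 1.0, 2.0, 3.0],
                            [0.0, 2.0, 3.5, 6.5]])
        cells = cell_frame(
            {"m1": np.expm1(logvals[0]), "m2": np.expm1(logvals[1])},
            times=(1.0, 2.0, 3.0, 4.0),
        )
        t = table_from_cells(cells, n_rep=1)
        _, explained = pca_ordinate(t)
        x = logvals - logvals.mean(axis=1, keepdims=True)
        a = (x[0] @ x[0]) / 3
        c = (x[1] @ x[1]) / 3
        b = (x[0] @ x[1]) / 3
        lam1 = ((a + c) + np.sqrt((a - c) ** 2 + 4 * b**2)) / 2
        lam2 = ((a + c) - np.sqrt((a - c) ** 2 + 4 * b**2)) / 2
        assert explained[0] == pytest.approx(lam1 / (lam1 + lam2))


def _ols_type2_oracle(y, is_killed, time):
    """From-scratch Type II F-tests for condition and condition:time."""
    from scipy.stats import f as fdist

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    one = np.ones_like(time)
    full = np.column_stack([one, is_killed, time, is_killed * time])
    no_int = full[:, :3]
    no_cond = np.column_stack([one, time])
    df_resid = len(y) - 4
    mse = rss(full) / df_resid
    f_cond = (rss(no_cond) - rss(no_int)) / mse
    f_int = (rss(no_int) - rss(full)) / mse
    return (fdist.sf(f_cond, 1, df_resid), fdist.sf(f_int, 1, df_resid))


class TestKilledControl:
    def test_identical_trajectories_not_significant(self):
        cells = cell_frame({"m": [1.0, 5.0, 2.0]}, stages=("D",))
        active = table_from_cells(cells, n_rep=4, condition="active")
        killed = table_from_cells(cells, n_rep=3, condition="killed")
        verdicts, _ = killed_control_test(active, killed)
        v = verdicts.loc["m"]
        assert v["detected_in_killed"]
        assert not v["biologically_controlled"]
        assert v["p_condition"] > 0.99

    def test_metabolite_absent_in_killed_is_controlled(self):
        active = table_from_cells(cell_frame({"m": [1, 2, 3],
                                              "x": [2, 2, 2]}),
                                  condition="active")
        killed = table_from_cells(cell_frame({"x": [2, 2, 2]}),
                                  condition="killed")
        verdicts, _ = killed_control_test(active, killed)
        assert not verdicts.loc["m", "detected_in_killed"]
        assert verdicts.loc["m", "biologically_controlled"]

    def test_consumed_metabolite_flagged_and_matches_oracle(self):
        """A strongly consumed metabolite differs from the killed
        control, and both F-test p-values match an independent
        lstsq-based Type II computation."""
        data = simulate_dataset(default_scenario(seed=7))
        verdicts, _ = killed_control_test(data.active, data.killed)
        v = verdicts.loc["glutamate"]
        assert v["biologically_controlled"]

        stage = data.scenario.killed_stage
        rows = []
        for tbl, cond in ((data.active, 0.0), (data.killed, 1.0)):
            meta = tbl.meta
            mask = (meta["stage"] == stage) if cond == 0.0 else np.ones(
                len(meta), dtype=bool)
            y = tbl.areas.loc["glutamate"].to_numpy(dtype=float)[mask]
            t = meta["time"].to_numpy(dtype=float)[mask]
            rows.append((np.log1p(y), np.full(y.shape, cond), t))
        y = np.concatenate([r[0] for r in rows])
        k = np.concatenate([r[1] for r in rows])
        t = np.concatenate([r[2] for r in rows])
        p_cond, p_int = _ols_type2_oracle(y, k, t)
        assert v["p_condition"] == pytest.approx(p_cond, rel=1e-6, abs=1e-12)
        assert v["p_interaction"] == pytest.approx(p_int, rel=1e-6, abs=1e-12)

    def test_single_observation_condition_unevaluable(self):
        active = table_from_cells(cell_frame({"m": [1, 2, 3]}),
                                  condition="active")
        killed = table_from_cells(cell_frame({"m": [1.0, np.nan, np.nan]},
                                             times=(1.0, 2.0, 3.0)),
                                  n_rep=1, condition="killed")
        verdicts, _ = killed_control_test(active, killed)
        assert not verdicts.loc["m", "evaluable"]

    def test_tukey_table_reported(self):
        rng = np.random.default_rng(15)
        cells = cell_frame({"m": [1.0, 5.0, 2.0]}, stages=("D",))
        active = table_from_cells(cells, n_rep=4)
        killed = table_from_cells(cells * 2, n_rep=3, condition="killed")
        for t in (active, killed):  # replicate jitter so groups have spread
            t.areas.iloc[:] *= rng.lognormal(0, 0.05, t.areas.shape)
        _, tukey = killed_control_test(active, killed, tukey=True)
        assert tukey is not None and len(tukey) > 0


class TestVerdictFlag:
    @pytest.mark.parametrize(
        "detected,p_cond,p_int,expected",
        [
            (False, np.nan, np.nan, True),
            (True, 0.01, 0.9, True),
            (True, 0.9, 0.01, True),
            (True, 0.2, 0.6, False),
        ],
    )
    def test_rule(self, detected, p_cond, p_int, expected):
        assert verdict_flag(detected, p_cond, p_int, alpha=0.05) is expected
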