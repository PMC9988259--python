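"""Partial correlations, choice-conditioned tuning and baseline comparisons."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from recalib.choice_analysis import (
    baseline_fr_comparison,
    choice_conditioned_tuning,
    compare_pre_post_partials,
    partial_correlations,
)


def _residual_oracle(fr, h, c):
    """Correlation of OLS residuals -- independent route to the partials."""
    def resid(y, x):
        X = np.c_[np.ones_like(x), x]
        return y - X @ np.linalg.lstsq(X, y, rcond=None)[0]

    r_h = np.corrcoef(resid(fr, c), resid(h, c))[0, 1]
    r_c = np.corrcoef(resid(fr, h), resid(c, h))[0, 1]
    return r_h, r_c


class TestPartialCorrelations:
    def test_matches_residual_oracle_and_pingouin(self, rng):
        for _ in range(20):
            n = int(rng.integers(12, 30))
            h = rng.choice([-8.0, -4.0, -1.0, 1.0, 4.0, 8.0], n)
            c = np.where(rng.random(n) < 0.5 + h / 20, 1.0, -1.0)
            if np.unique(c).size < 2:
                continue
            fr = 20 + 0.5 * h + 2.0 * c + rng.normal(0, 3, n)
            res = partial_correlations(fr, h, c)
            r_h, r_c = _residual_oracle(fr, h, c)
            assert res.r_h == pytest.approx(r_h, abs=1e-10)
            assert res.r_c == pytest.approx(r_c, abs=1e-10)
            df = pd.DataFrame({"fr": fr, "h": h, "c": c})
            pg_h = pg.partial_corr(df, x="fr", y="h", covar="c")
            assert res.r_h == pytest.approx(float(pg_h["r"].iloc[0]), abs=1e-8)
            assert res.p_h == pytest.approx(float(pg_h["p_val"].iloc[0]), abs=1e-8)

    def test_heading_only_signal(self, rng):
        h = np.tile([-8.0, -2.0, 2.0, 8.0], 50)
        c = rng.choice([-1.0, 1.0], h.size)  # coin-flip choices
        fr = 1.5 * h + rng.normal(0, 2, h.size)
        res = partial_correlations(fr, h, c)
        assert res.r_h > 0.8 and abs(res.r_c) < 0.2

    def test_choice_only_signal(self, rng):
        h = np.tile([-8.0, -2.0, 2.0, 8.0], 50)
        c = rng.choice([-1.0, 1.0], h.size)
        fr = 3.0 * c + rng.normal(0, 2, h.size)
        res = partial_correlations(fr, h, c)
        assert res.r_c > 0.6 and abs(res.r_h) < 0.2

    def test_choice_code_invariance(self, rng):
        h = np.tile([-4.0, 4.0], 20)
        c = rng.choice([-1.0, 1.0], h.size)
        fr = 10 + h + 2 * c + rng.normal(0, 1, h.size)
        r1 = partial_correlations(fr, h, c).r_c
        r2 = partial_correlations(fr, h, (c + 1) / 2).r_c  # 0/1 coding
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_single_choice_class_rejected(self):
        with pytest.raises(ValueError, match="both choices"):
            partial_correlations(np.arange(12.0), np.arange(12.0), np.ones(12))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match=">=10"):
            partial_correlations(np.arange(5.0), np.arange(5.0), np.array([1, -1, 1, -1, 1]))


class TestChoiceConditionedTuning:
    def test_weighted_mean_identity(self, rng):
        h = rng.choice([-8.0, -1.0, 1.0, 8.0], 200)
        c = rng.choice(["left", "right"], 200)
        fr = rng.normal(20, 5, 200)
        out = choice_conditioned_tuning(fr, h, c, min_count=1)
        for hh in np.unique(h):
            cells = out[(out.heading_deg == hh) & (out.choice != "all")]
            overall = out[(out.heading_deg == hh) & (out.choice == "all")].iloc[0]
            wmean = np.sum(cells.mean_fr_hz * cells.n) / cells.n.sum()
            assert overall.mean_fr_hz == pytest.approx(wmean, abs=1e-10)

    def test_positive_choice_gain_orders_curves(self, rng):
        h = np.tile([-8.0, -2.0, 2.0, 8.0], 100)
        c = rng.choice(["left", "right"], h.size)
        fr = 20 + 0.5 * h + np.where(c == "right", 3.0, -3.0) + rng.normal(0, 1, h.size)
        out = choice_conditioned_tuning(fr, h, c)
        for hh in np.unique(h):
            r = out[(out.heading_deg == hh) & (out.choice == "right")].mean_fr_hz.iloc[0]
            l = out[(out.heading_deg == hh) & (out.choice == "left")].mean_fr_hz.iloc[0]
            assert r > l

    def test_sparse_cells_masked(self):
        out = choice_conditioned_tuning(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0]),
            np.array(["left", "right", "right"]), min_count=3,
        )
        masked = out[out.choice != "all"]
        assert masked.masked.all() and masked.mean_fr_hz.isna().all()


class TestPrePostComparison:
    @staticmethod
    def _partials(rc_pre, rc_post, n=10):
        rows = []
        for i in range(n):
            for block, val in (("pre", rc_pre), ("post", rc_post)):
                rows.append(
                    {"neuron_id": f"n{i}", "cue": "vestibular", "block": block,
                     "r_h": 0.4 + 0.01 * i, "r_c": val + 0.01 * i}
                )
        return pd.DataFrame(rows)

    def test_identical_blocks_give_zero_difference(self):
        out = compare_pre_post_partials(self._partials(0.5, 0.5))
        assert (out.mean_diff == 0).all()

    def test_reduced_choice_signal_detected(self):
        out = compare_pre_post_partials(self._partials(0.6, 0.3))
        row = out[(out.quantity == "r_c_sq")].iloc[0]
        assert row.mean_diff < 0 and row.p < 0.01
        assert out[(out.quantity == "r_h_sq")].iloc[0].mean_diff == 0

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError, match=">=5"):
            compare_pre_post_partials(self._partials(0.5, 0.5, n=3))


class TestBaselineComparison:
    def test_identical_baselines(self):
        out = baseline_fr_comparison(np.full(20, 11.0), np.full(20, 11.0))
        assert out["mean_diff_hz"] == 0.0

    def test_injected_offset_detected(self, rng):
        pre = rng.normal(20, 1, 50)
        out = baseline_fr_comparison(pre, pre + 2 + rng.normal(0, 1, 50))
        assert out["p"] < 0.05 and out["mean_diff_hz"] == pytest.approx(2.0, abs=0.6)
        lo, hi = out["ci95_hz"]
        assert lo < out["mean_diff_hz"] < hi

    def test_null_false_positive_rate(self):
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            rng = np.random.default_rng(i)
            pre = rng.normal(20, 2, 30)
            post = pre + rng.normal(0, 1, 30)
            hits += baseline_fr_comparison(pre, post)["p"] < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.04)
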