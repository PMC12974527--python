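"""Decay fitting, variance shrinkage, moderated testing and tier calling."""

import subprocess
import sys
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import protstab as ps
from protstab.decay import ShrinkagePrior


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def grid_search_slope(times, values, lo=-5.0, hi=5.0, n=200001):
    """Brute-force slope: argmin over a dense slope grid of the SSE with
    the intercept profiled out."""
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    grid = np.linspace(lo, hi, n)
    resid = y[None, :] - grid[:, None] * t[None, :]
    sse = np.sum((resid - resid.mean(axis=1, keepdims=True)) ** 2, axis=1)
    return grid[np.argmin(sse)]


def bh_brute_force(p):
    """Direct step-up definition: q_i = min over {j : p_j >= p_i} of
    min(1, m * p_j / rank_j) with ascending 1-based ranks."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m)
    ranks[order] = np.arange(1, m + 1)
    # for ties use the largest rank among equal p (matches step-up outcome)
    for i in range(m):
        ranks[i] = np.sum(p <= p[i])
    q = np.empty(m)
    for i in range(m):
        candidates = [min(1.0, m * p[j] / ranks[j])
                      for j in range(m) if p[j] >= p[i]]
        q[i] = min(candidates)
    return q


class TestFitProteinDecay:
    def test_noiseless_two_hour_halflife(self):
        t = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        y = 20.0 - t / 2.0          # log2 scale, t_half = 2 h
        beta0, beta1, s2, df, r2, u = ps.fit_protein_decay(t, y)
        assert beta1 == pytest.approx(-0.5, abs=1e-12)
        assert -1.0 / beta1 == pytest.approx(2.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_constant_trace(self):
        t = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.full(4, 12.0)
        beta0, beta1, s2, df, r2, u = ps.fit_protein_decay(t, y)
        assert beta1 == 0.0
        assert r2 == 0.0

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(0)
        t = np.tile([0.0, 0.5, 1.0, 2.0, 4.0], 2)
        for _ in range(10):
            y = 15 + rng.uniform(-2, 0) * t + rng.normal(0, 0.3, t.size)
            _, beta1, *_ = ps.fit_protein_decay(t, y)
            assert beta1 == pytest.approx(grid_search_slope(t, y), abs=1e-4)

    def test_too_few_observations_skipped(self):
        assert ps.fit_protein_decay([0, 1, 2], [1.0, 2.0, 3.0], min_obs=4) is None
        # four observations but a single distinct time
        assert ps.fit_protein_decay([1, 1, 1, 1], [1, 2, 3, 4]) is None

    def test_lower_noise_never_worsens_halflife_rmse(self):
        rmses = []
        for noise in (0.3, 0.15, 0.05):
            spec = ps.DecaySimSpec(n_proteins=300, frac_unstable=0.4,
                                   halflife_range_unstable=(0.5, 4.0),
                                   noise_sd=noise, seed=77)
            m, truth = ps.simulate_decay_matrix(spec)
            fits, _ = ps.fit_decay_matrix(ps.log2_transform(m))
            merged = fits.merge(truth, on="protein_id")
            un = merged[merged["is_unstable"]]
            rel = (-1.0 / un["beta1"] - un["true_halflife"]) / un["true_halflife"]
            rmses.append(np.sqrt(np.mean(rel ** 2)))
        assert rmses[0] >= rmses[1] >= rmses[2]

    def test_halflife_rate_identity(self):
        spec = ps.DecaySimSpec(n_proteins=100, frac_unstable=0.5, noise_sd=0.2,
                               seed=2)
        m, _ = ps.simulate_decay_matrix(spec)
        res, _ = ps.analyze_matrix(ps.log2_transform(m))
        decaying = res[res["beta1"] < 0]
        assert np.allclose(decaying["k"] * decaying["halflife_h"], np.log(2.0))


class TestPriorEstimation:
    def test_recovers_known_prior_within_25_percent(self):
        rng = np.random.default_rng(3)
        n, df, d0, s0_2 = 5000, 8, 4.0, 0.02
        sigma2 = s0_2 * d0 / rng.chisquare(d0, size=n)
        s2 = sigma2 * rng.chisquare(df, size=n) / df
        prior = ps.estimate_prior(s2, np.full(n, df))
        assert abs(prior.d0 - d0) / d0 < 0.25
        assert abs(prior.s0_2 - s0_2) / s0_2 < 0.25

    def test_identical_variances_give_infinite_d0(self):
        prior = ps.estimate_prior(np.full(50, 0.3), np.full(50, 6))
        assert np.isinf(prior.d0)
        assert prior.s0_2 == pytest.approx(0.3)

    def test_heterogeneous_small_sample_gives_finite_positive_d0(self):
        rng = np.random.default_rng(4)
        s2 = rng.chisquare(3, size=10)
        prior = ps.estimate_prior(s2, np.full(10, 3))
        assert 0 < prior.d0 < np.inf

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ps.InputError):
            ps.estimate_prior(np.zeros(20), np.full(20, 5))

    def test_matches_limma_squeeze(self, tmp_path):
        """Cross-check prior estimation and moderated p against limma."""
        rng = np.random.default_rng(5)
        n, df = 200, 8
        sigma2 = 0.05 * 5.0 / rng.chisquare(5.0, size=n)
        s2 = sigma2 * rng.chisquare(df, size=n) / df
        np.savetxt(tmp_path / "s2.txt", s2)
        script = tmp_path / "squeeze.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f's2 <- scan("{tmp_path / "s2.txt"}", quiet=TRUE)\n'
            f'sq <- squeezeVar(s2, df={df})\n'
            'cat(sq$df.prior, sq$var.prior, paste(sq$var.post, collapse=","),'
            ' sep="\\n")\n')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout.strip().splitlines()
        d0_ref, s02_ref = float(out[0]), float(out[1])
        post_ref = np.array([float(x) for x in out[2].split(",")])
        prior = ps.estimate_prior(s2, np.full(n, df))
        assert prior.d0 == pytest.approx(d0_ref, rel=1e-6)
        assert prior.s0_2 == pytest.approx(s02_ref, rel=1e-6)
        fits = pd.DataFrame({"beta1": np.zeros(n), "s2": s2,
                             "df_resid": np.full(n, df),
                             "se_unscaled": np.ones(n)})
        mod = ps.moderate_and_test(fits, prior)
        assert np.allclose(mod["s2_tilde"].to_numpy(), post_ref, rtol=1e-6)


class TestModeratedT:
    def test_squeeze_formula(self):
        fits = pd.DataFrame({"beta1": [-1.0], "s2": [2.0], "df_resid": [3],
                             "se_unscaled": [1.0]})
        mod = ps.moderate_and_test(fits, ShrinkagePrior(d0=3.0, s0_2=1.0))
        assert mod["s2_tilde"].iloc[0] == pytest.approx(1.5)

    def test_d0_zero_recovers_ordinary_t(self):
        rng = np.random.default_rng(6)
        fits = pd.DataFrame({"beta1": rng.normal(size=20),
                             "s2": rng.chisquare(5, 20),
                             "df_resid": np.full(20, 5),
                             "se_unscaled": np.full(20, 0.3)})
        mod = ps.moderate_and_test(fits, ShrinkagePrior(d0=1e-12, s0_2=1.0))
        t_ord = fits["beta1"] / (0.3 * np.sqrt(fits["s2"]))
        assert np.allclose(mod["t_mod"], t_ord, rtol=1e-6)

    def test_infinite_d0_shares_prior_variance(self):
        fits = pd.DataFrame({"beta1": [-1.0, 2.0], "s2": [0.5, 3.0],
                             "df_resid": [4, 4], "se_unscaled": [1.0, 1.0]})
        mod = ps.moderate_and_test(fits, ShrinkagePrior(d0=np.inf, s0_2=0.7))
        assert (mod["s2_tilde"] == 0.7).all()
        # infinite df: p equals the normal tail
        z = mod["t_mod"].iloc[0]
        assert mod["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(abs(z)))


class TestBHAdjustment:
    def test_single_p(self):
        assert ps.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        q = ps.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ps.InputError):
            ps.bh_adjust([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_matches_brute_force_and_preserves_order(self, p):
        q = ps.bh_adjust(p)
        assert np.allclose(q, bh_brute_force(p), atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()


class TestTierCalling:
    def _results(self, halflife, q, r2):
        beta1 = -1.0 / halflife if np.isfinite(halflife) else 0.0
        return pd.DataFrame({"protein_id": ["X"], "beta1": [beta1],
                             "s2": [0.1], "df_resid": [8], "r2": [r2],
                             "se_unscaled": [0.2], "p": [q]})

    def test_all_criteria_met(self):
        res = ps.call_tiers(self._results(3.9, 0.01, 0.6),
                            ps.DecayModelConfig(), window_h=4.0)
        assert res["tier"].iloc[0] == "high_confidence"

    def test_r2_gate(self):
        res = ps.call_tiers(self._results(3.9, 0.01, 0.4),
                            ps.DecayModelConfig(), window_h=4.0)
        assert res["tier"].iloc[0] == "screen_hit"

    def test_increasing_trace_stays_stable(self):
        fits = pd.DataFrame({"protein_id": ["X"], "beta1": [0.5], "s2": [0.1],
                             "df_resid": [8], "r2": [0.9],
                             "se_unscaled": [0.2], "p": [1e-6]})
        res = ps.call_tiers(fits, ps.DecayModelConfig(), window_h=4.0)
        assert res["tier"].iloc[0] == "stable"
        assert res["halflife_h"].iloc[0] == np.inf

    def test_window_sets_default_halflife_cutoff(self):
        res8 = ps.call_tiers(self._results(6.0, 0.001, 0.9),
                             ps.DecayModelConfig(), window_h=8.0)
        res4 = ps.call_tiers(self._results(6.0, 0.001, 0.9),
                             ps.DecayModelConfig(), window_h=4.0)
        assert res8["tier"].iloc[0] == "high_confidence"
        assert res4["tier"].iloc[0] == "stable"


class TestMLLabel:
    def _res(self, pids, qs, fcs):
        return pd.DataFrame({"protein_id": pids, "q": qs, "log2fc_window": fcs})

    def test_either_dataset_rule(self):
        exp = self._res(["A"], [0.01], [-0.8])
        stat = self._res(["A"], [0.8], [0.0])
        labels = ps.ml_label([exp, stat])
        assert labels["A"] == 1

    def test_fold_change_gate(self):
        exp = self._res(["A"], [0.01], [-0.3])
        stat = self._res(["A"], [0.01], [-0.3])
        assert ps.ml_label([exp, stat])["A"] == 0

    def test_matches_set_logic_oracle(self):
        rng = np.random.default_rng(7)
        pids = [f"P{i}" for i in range(200)]
        exp = self._res(pids, rng.uniform(0, 0.2, 200), rng.uniform(-1, 0, 200))
        stat = self._res(pids[:150], rng.uniform(0, 0.2, 150),
                         rng.uniform(-1, 0, 150))
        labels = ps.ml_label([exp, stat])
        expect = set()
        for res in (exp, stat):
            for _, r in res.iterrows():
                if r["q"] < 0.05 and r["log2fc_window"] < -0.5:
                    expect.add(r["protein_id"])
        assert {p for p, v in labels.items() if v == 1} == expect
        assert set(labels.index) == set(pids)

    def test_duplicate_ids_rejected(self):
        bad = self._res(["A", "A"], [0.01, 0.2], [-0.8, 0.0])
        with pytest.raises(ps.InputError):
            ps.ml_label([bad])
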