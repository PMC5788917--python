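import numpy as np
import pandas as pd
import pytest

from peershift import (
    MCMCConfig,
    ModelSpec,
    PosteriorSamples,
    all_contrasts,
    contrast,
    effective_sample_size,
    fit_check,
    gelman_rubin,
    summarize,
)
from peershift.diagnostics import DiagnosticError, _summarize_array

from conftest import make_tiny_dataset


def make_samples(arrays_by_name, spec=None):
    """PosteriorSamples from {name: (n_chains, n_kept) array}."""
    names = list(arrays_by_name)
    stacked = np.stack([np.asarray(arrays_by_name[n], float) for n in names], axis=2)
    conditions = [n[5:-1] for n in names if n.startswith("beta[")]
    pids = list(dict.fromkeys(n[2:-1].split(",")[0] for n in names if n.startswith("u[")))
    return PosteriorSamples(
        stacked, names, spec if spec is not None else ModelSpec(), None, conditions, pids
    )


class TestGelmanRubin:
    def test_identical_chains_degenerate_value(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=500)
        point, upper = gelman_rubin(np.stack([chain, chain]))
        assert point == pytest.approx(np.sqrt(499 / 500))
        assert point < 1.0
        assert upper == pytest.approx(point)

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(1)
        point, upper = gelman_rubin(rng.normal(size=(3, 10_000)))
        assert 0.99 <= point <= 1.01
        assert upper >= point

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 1_000))
        chains[1] += 10.0
        point, _ = gelman_rubin(chains)
        assert point > 3.0

    def test_single_chain_rejected(self):
        with pytest.raises(DiagnosticError):
            gelman_rubin(np.zeros((1, 100)))

    def test_offset_chains_worse_than_split_pool(self):
        rng = np.random.default_rng(3)
        pooled = rng.normal(size=2_000)
        split = pooled.reshape(2, 1_000)
        offset = split.copy()
        offset[1] += 2.0
        assert gelman_rubin(split)[0] <= gelman_rubin(offset)[0]


class TestEffectiveSampleSize:
    def test_white_noise_ess_near_total(self):
        rng = np.random.default_rng(4)
        ess = effective_sample_size(rng.normal(size=(3, 5_000)))
        assert 13_500 <= ess <= 16_500

    def test_ar1_matches_closed_form(self):
        rho, n = 0.9, 15_000
        rng = np.random.default_rng(5)
        x = np.empty(n)
        x[0] = rng.normal()
        innov = rng.normal(size=n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + innov[i]
        ess = effective_sample_size(x[None, :])
        expected = n * (1 - rho) / (1 + rho)
        assert abs(ess - expected) / expected < 0.25

    def test_reversal_invariance(self):
        rng = np.random.default_rng(6)
        chains = rng.normal(size=(2, 2_000)).cumsum(axis=1)  # autocorrelated
        assert effective_sample_size(chains) == pytest.approx(
            effective_sample_size(chains[:, ::-1])
        )

    def test_constant_chain_warns_and_returns_n(self):
        with pytest.warns(UserWarning, match="constant"):
            assert effective_sample_size(np.ones((1, 200))) == 200.0


class TestSummarize:
    def test_integer_sequence_quantiles(self):
        samples = make_samples({"beta[face]": np.arange(1.0, 101.0).reshape(2, 50)})
        row = summarize(samples).loc["beta[face]"]
        assert row["median"] == pytest.approx(50.5)
        assert row["lower"] == pytest.approx(3.475)
        assert row["upper"] == pytest.approx(97.525)

    def test_degenerate_draws(self):
        samples = make_samples({"phi": np.full((2, 50), 7.0)})
        row = summarize(samples).loc["phi"]
        assert row["median"] == row["lower"] == row["upper"] == 7.0

    def test_chain_relabelling_invariance(self):
        rng = np.random.default_rng(7)
        arr = rng.normal(size=(3, 200))
        a = summarize(make_samples({"phi": arr}))
        b = summarize(make_samples({"phi": arr[::-1]}))
        pd.testing.assert_frame_equal(a, b)

    def test_interval_nesting_in_level(self):
        rng = np.random.default_rng(8)
        samples = make_samples({"phi": rng.normal(size=(2, 500))})
        s90 = summarize(samples, 0.90).loc["phi"]
        s95 = summarize(samples, 0.95).loc["phi"]
        s99 = summarize(samples, 0.99).loc["phi"]
        assert s99["lower"] <= s95["lower"] <= s90["lower"]
        assert s90["upper"] <= s95["upper"] <= s99["upper"]

    def test_ess_bounded_by_total_draws(self):
        rng = np.random.default_rng(9)
        samples = make_samples({"phi": rng.normal(size=(3, 400))})
        row = summarize(samples).loc["phi"]
        assert row["ess"] <= 3 * 400


class TestContrast:
    def test_self_contrast_is_zero(self):
        rng = np.random.default_rng(10)
        samples = make_samples({"beta[face]": rng.normal(size=(2, 100))})
        row = contrast(samples, "face", "face")
        assert row["median"] == row["lower"] == row["upper"] == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        samples = make_samples(
            {
                "beta[face]": rng.normal(size=(2, 300)),
                "beta[hand]": rng.normal(size=(2, 300)),
            }
        )
        ab = contrast(samples, "face", "hand")
        ba = contrast(samples, "hand", "face")
        assert ab["median"] == pytest.approx(-ba["median"])
        assert ab["lower"] == pytest.approx(-ba["upper"])

    def test_equals_summary_of_difference_series(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=(2, 2, 300))
        samples = make_samples({"beta[face]": a, "beta[hand]": b})
        row = contrast(samples, "face", "hand")
        direct = _summarize_array(a - b, 0.95)
        for key, val in direct.items():
            assert row[key] == pytest.approx(val, nan_ok=True)

    def test_unknown_condition_rejected(self):
        samples = make_samples({"beta[face]": np.zeros((2, 50))})
        with pytest.raises(KeyError):
            contrast(samples, "face", "hand")

    def test_all_contrasts_has_one_row_per_pair(self):
        rng = np.random.default_rng(13)
        samples = make_samples(
            {f"beta[{c}]": rng.normal(size=(2, 50)) for c in ("face", "hand", "art")}
        )
        out = all_contrasts(samples)
        assert list(out.index) == [
            "beta[face]-beta[hand]",
            "beta[face]-beta[art]",
            "beta[hand]-beta[art]",
        ]


class TestFitCheck:
    def _constant_samples_for(self, dataset, beta=0.0):
        pids = list(dataset.participants["participant_id"])
        arrays = {f"beta[{c}]": np.full((2, 20), beta) for c in ("face", "hand", "art")}
        arrays.update({f"u[{p}]": np.zeros((2, 20)) for p in pids})
        arrays["sigma_u2"] = np.full((2, 20), 0.06)
        arrays["phi"] = np.full((2, 20), 20.0)
        return make_samples(arrays)

    def test_perfect_predictions(self):
        # With s = 0 the prediction is the initial rating; a dataset whose
        # final ratings equal its initial ratings is predicted perfectly.
        ds = make_tiny_dataset(n_participants=4, n_images=6, seed=3)
        trials = ds.trials.copy()
        trials["final_raw"] = trials["initial_raw"]
        from peershift import Dataset

        ds2 = Dataset(trials, ds.participants)
        check = fit_check(self._constant_samples_for(ds2), ds2)
        assert check.correlation == pytest.approx(1.0, abs=1e-9)
        assert check.pseudo_r2 == pytest.approx(check.correlation**2, abs=1e-12)

    def test_independent_predictions_uncorrelated(self):
        # Final ratings independent of everything else: correlation near 0.
        ds = make_tiny_dataset(n_participants=10, n_images=102, seed=14)
        assert ds.n_trials >= 1_000
        check = fit_check(self._constant_samples_for(ds), ds)
        assert abs(check.correlation) < 0.1

    def test_zero_variance_observations_rejected(self):
        ds = make_tiny_dataset(n_participants=3, n_images=3, seed=2)
        trials = ds.trials.copy()
        trials["final_raw"] = 50.0
        from peershift import Dataset

        with pytest.raises(DiagnosticError, match="zero variance"):
            fit_check(self._constant_samples_for(ds), Dataset(trials, ds.participants))
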