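"""Fit cost structure and the Metropolis ensemble sampler."""

import numpy as np
import pytest

import per2as.fitting as fitting
from per2as.fitting import (
    FitConstraints,
    MutantBehaviour,
    ensemble_fit,
    fit_cost,
)
from per2as.model import MutantSpec
from per2as.synthetic import generate_model_dataset


@pytest.fixture(autouse=True)
def fast_fit_simulations(monkeypatch):
    """Shorter fitting simulations: structural properties do not need the
    analysis-grade window."""
    monkeypatch.setattr(fitting, "_FIT_SIM",
                        dict(t_end=560.0, transient=400.0, dt=0.1))


@pytest.fixture(scope="module")
def wt_dataset(wt):
    return generate_model_dataset("pre", wt, noise_sd=0.0, seed=0,
                                  n_days=2, sampling_interval=2.0)


class TestFitCost:
    def test_self_consistency_cost_is_near_zero(self, wt, wt_dataset,
                                                monkeypatch):
        # compare attractor-to-attractor: both the dataset and the fit
        # simulation past the settling time of the wild-type cycle
        settled = generate_model_dataset("pre", wt, noise_sd=0.0, seed=0,
                                         n_days=2, sampling_interval=2.0,
                                         transient=1500.0)
        monkeypatch.setattr(fitting, "_FIT_SIM",
                            dict(t_end=1740.0, transient=1500.0, dt=0.1))
        cost = fit_cost(wt, settled, FitConstraints())
        assert cost < 1e-3

    def test_perturbed_parameters_cost_more(self, wt, wt_dataset):
        base = fit_cost(wt, wt_dataset, FitConstraints())
        worse = fit_cost(wt.replace(K_S=wt["K_S"] * 4.0, d_AS=wt["d_AS"] / 3.0),
                         wt_dataset, FitConstraints())
        assert worse > base

    def test_failed_regime_returns_finite_sentinel(self, wt, wt_dataset):
        # non-oscillatory parameters must not raise inside a sampler
        cost = fit_cost(wt.replace(mu=0.2), wt_dataset, FitConstraints())
        assert np.isfinite(cost)
        assert cost >= fitting.FAILED_SIMULATION_COST

    def test_cost_is_order_free_in_dataset_rows(self, wt, wt_dataset):
        from per2as.synthetic import TimecourseDataset

        # same data, species listed in the opposite order
        reordered = TimecourseDataset(
            wt_dataset.times,
            dict(reversed(list(wt_dataset.values.items()))),
            wt_dataset.metadata)
        c1 = fit_cost(wt, wt_dataset, FitConstraints())
        c2 = fit_cost(wt, reordered, FitConstraints())
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_mutant_behaviour_penalty(self, wt, wt_dataset):
        # demand (falsely) that the WT clock must NOT oscillate
        constraints = FitConstraints(
            mutant_behaviours=(MutantBehaviour(MutantSpec(), False),),
            weight_mutant=7.0)
        base = fit_cost(wt, wt_dataset, FitConstraints())
        penalized = fit_cost(wt, wt_dataset, constraints)
        assert penalized == pytest.approx(base + 7.0, abs=1e-6)

    def test_gaussian_noise_inflates_timecourse_term_by_its_variance(
            self, wt, wt_pre_traj, wt_dataset):
        """Monte-Carlo oracle for the time-course term.

        Two checks over 50 noise realizations: (i) the term agrees with an
        independent literal re-implementation of "peak-normalized MSE at
        the best circular shift", and (ii) its mean is of the order of the
        injected noise variance sigma^2 (peak re-normalization of noisy
        data inflates it somewhat, so the law is asserted as a band)."""
        from per2as.fitting import _timecourse_sse
        from per2as.synthetic import TimecourseDataset

        def literal_term(traj, ds):
            from per2as.rhythms import measure_period

            T = measure_period(traj, "Per2")
            t_rel = traj.times - traj.times[0]
            shifts = np.linspace(0.0, T, 64, endpoint=False)
            best = np.inf
            n_res = sum(len(v) for v in ds.values.values())
            for s in shifts:
                total = 0.0
                for sp, data in ds.values.items():
                    xn = traj.column(sp) / traj.column(sp).max()
                    dn = np.asarray(data) / np.max(data)
                    model = np.interp((ds.times + s) % T, t_rel, xn)
                    total += np.sum((model - dn) ** 2)
                best = min(best, total / n_res)
            return best

        sigma = 0.08
        clean = wt_dataset
        vals = []
        for seed in range(50):
            local = np.random.default_rng(seed)
            noisy = TimecourseDataset(
                clean.times,
                {sp: v + local.normal(0, sigma, size=v.shape)
                 for sp, v in clean.values.items()},
                dict(clean.metadata, noise_sd=sigma))
            term = _timecourse_sse(wt_pre_traj, noisy)
            # the production path additionally refines the best shift, so it
            # may only improve on the literal grid search
            grid_val = literal_term(wt_pre_traj, noisy)
            assert term <= grid_val + 1e-12
            assert term == pytest.approx(grid_val, rel=0.15)
            vals.append(term)
        assert 0.5 * sigma ** 2 < np.mean(vals) < 3.0 * sigma ** 2


class TestEnsembleFit:
    BOUNDS = {"K_S": (0.05, 0.5), "d_AS": (1.0, 7.0)}

    def test_identical_seeds_give_identical_ensembles(self, wt, wt_dataset):
        kw = dict(free_params=["K_S", "d_AS"], bounds=self.BOUNDS,
                  n_steps=12, seed=3, start=wt, threshold=10.0)
        a = ensemble_fit(wt_dataset, FitConstraints(), **kw)
        b = ensemble_fit(wt_dataset, FitConstraints(), **kw)
        fa, fb = a.parameter_frame(), b.parameter_frame()
        assert fa.equals(fb)
        assert a.n_moves == b.n_moves

    def test_zero_temperature_descends_monotonically(self, wt, wt_dataset):
        result = ensemble_fit(wt_dataset, FitConstraints(),
                              free_params=["K_S"], bounds=self.BOUNDS,
                              n_steps=25, temperature=0.0, seed=5,
                              start=wt.replace(K_S=0.3), threshold=1e9)
        costs = [c for _, c in result.accepted]
        assert all(b <= a + 1e-12 for a, b in zip(costs, costs[1:]))

    def test_invalid_inputs_rejected(self, wt, wt_dataset):
        with pytest.raises(KeyError):
            ensemble_fit(wt_dataset, FitConstraints(),
                         free_params=["nope"], bounds={"nope": (0.1, 1)},
                         n_steps=5, seed=0, start=wt)
        with pytest.raises(ValueError):
            ensemble_fit(wt_dataset, FitConstraints(),
                         free_params=["K_S"], bounds={"K_S": (0.5, 0.1)},
                         n_steps=5, seed=0, start=wt)

    def test_accepted_sets_respect_threshold(self, wt, wt_dataset):
        result = ensemble_fit(wt_dataset, FitConstraints(),
                              free_params=["K_S"], bounds=self.BOUNDS,
                              n_steps=15, seed=7, start=wt, threshold=0.5)
        assert all(c <= 0.5 for _, c in result.accepted)
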