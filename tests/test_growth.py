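import numpy as np
import pandas as pd
import pytest

from nivalis.growth import (
    GrowthMCMC,
    GrowthModelSpec,
    GrowthSurvivalModel,
    monomolecular,
    phenology_regression,
    population_survival_shift,
    posterior_birth_dates,
    posterior_predictive_check,
    selection_on_adult_mass,
)


def make_captures(a, k, t0, days, mother="M0", year=2008, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, (ai, ki, ti) in enumerate(zip(np.atleast_1d(a), np.atleast_1d(k),
                                         np.atleast_1d(t0))):
        for d in days:
            if d - ti < 25:
                continue
            rows.append(
                dict(id=f"J{i}", mother=mother, year=year, julian_day=int(d),
                     mass=float(monomolecular(d, ai, ki, ti) + rng.normal(0, noise)))
            )
    return pd.DataFrame(rows)


SNOW = pd.DataFrame({"year": [2008], "snowmelt_day": [125.0],
                     "first_snowfall_day": [268.0]})


def make_survival(ids, survived=None, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {"id": ids, "sex": ["F"] * len(ids),
         "survived": survived if survived is not None else rng.integers(0, 2, len(ids))}
    )


class TestCurve:
    def test_strictly_increasing_to_asymptote(self):
        t = np.linspace(150, 600, 400)
        m = monomolecular(t, 42.0, 0.023, 150.0)
        assert np.all(np.diff(m) > 0)
        assert m[-1] < 42.0
        assert monomolecular(5000.0, 42.0, 0.023, 150.0) == pytest.approx(42.0, abs=1e-4)

    def test_zero_at_onset(self):
        assert monomolecular(160.0, 42.0, 0.02, 160.0) == 0.0


class TestFitBasics:
    def test_noise_free_trajectories_recover_parameters(self):
        rng = np.random.default_rng(11)
        n = 30
        a = rng.normal(42, 4, n)
        k = np.exp(rng.normal(np.log(0.023), 0.2, n))
        caps = make_captures(a, k, np.full(n, 160.0), (190, 215, 240, 265))
        model = GrowthSurvivalModel(
            spec=GrowthModelSpec(include_snow_interaction=False),
            mcmc=GrowthMCMC(iterations=4000, burnin=1500, thin=5, n_chains=1, seed=1),
        )
        model.fit(caps, SNOW, make_survival(caps["id"].unique()))
        post = model.posterior_
        lo, hi = np.percentile(post.a, [2.5, 97.5], axis=0)
        order = [int(i[1:]) for i in post.juveniles["id"]]
        covered = np.mean((a[order] >= lo) & (a[order] <= hi))
        assert covered >= 0.9
        assert abs(post.t0.mean() - 160.0) < 6.0

    def test_single_late_capture_tracks_observed_mass(self):
        # one capture long after onset with fast growth: a ~ observed mass
        caps = make_captures([40.0], [0.15], [150.0], (260,))
        model = GrowthSurvivalModel(
            spec=GrowthModelSpec(include_snow_interaction=False),
            mcmc=GrowthMCMC(iterations=1500, burnin=500, thin=5, n_chains=1, seed=2),
        )
        model.fit(caps, SNOW, make_survival(["J0"], [1]))
        a_post = model.posterior_.a.mean()
        assert abs(a_post - caps["mass"].iloc[0]) < 4.0

    def test_capture_before_snowmelt_rejected(self):
        caps = make_captures([40.0], [0.02], [150.0], (200,))
        caps.loc[0, "julian_day"] = 100
        with pytest.raises(ValueError, match="predate"):
            GrowthSurvivalModel(mcmc=GrowthMCMC(iterations=10, burnin=0, thin=1)).fit(
                caps, SNOW, make_survival(["J0"])
            )

    def test_snowfall_before_snowmelt_rejected(self):
        bad = SNOW.copy()
        bad["first_snowfall_day"] = 100.0
        caps = make_captures([40.0], [0.02], [150.0], (200,))
        with pytest.raises(ValueError, match="snowfall before snowmelt"):
            GrowthSurvivalModel(mcmc=GrowthMCMC(iterations=10, burnin=0, thin=1)).fit(
                caps, bad, make_survival(["J0"])
            )

    def test_missing_survival_outcome_rejected(self):
        caps = make_captures([40.0, 41.0], [0.02, 0.02], [150.0, 150.0], (200, 230))
        with pytest.raises(ValueError, match="survival outcome missing"):
            GrowthSurvivalModel(mcmc=GrowthMCMC(iterations=10, burnin=0, thin=1)).fit(
                caps, SNOW, make_survival(["J0"])
            )


class TestConstraints:
    def test_litter_constraints_hold_in_every_stored_state(self, growth_fit):
        _, post = growth_fit
        L = post.litter_dates.shape[2]
        assert L <= 5
        spacing = np.diff(post.litter_dates, axis=2)
        assert spacing.min() >= 20.0 - 1e-9
        assert post.assign.min() >= 0 and post.assign.max() < L

    def test_assignments_are_valid_partitions(self, growth_fit):
        ds, post = growth_fit
        # every juvenile's onset equals its assigned slot's date
        juv = post.juveniles
        keys = sorted(juv.groupby(["mother", "year"]).indices)
        g_of = {kk: i for i, kk in enumerate(keys)}
        gj = np.array([g_of[(m, y)] for m, y in zip(juv["mother"], juv["year"])])
        for s in range(0, post.n_samples, max(post.n_samples // 10, 1)):
            t0 = post.litter_dates[s, gj, post.assign[s]]
            assert np.allclose(t0, post.t0[s])


class TestDerivedOutputs:
    def test_selection_groups_and_curves(self, growth_fit):
        ds, post = growth_fit
        years = sorted(ds.captures["year"].unique())
        sel = selection_on_adult_mass(post, {"early": years[:2], "late": years[2:]})
        for r in sel.values():
            assert len(r["a_grid"]) == len(r["survival_curve"])
            assert np.all((r["survival_curve"] >= 0) & (r["survival_curve"] <= 1))

    def test_empty_group_raises(self, growth_fit):
        _, post = growth_fit
        with pytest.raises(ValueError, match="no juveniles"):
            selection_on_adult_mass(post, {"none": [1900]})

    def test_population_shift_zero_delta_is_zero(self, growth_fit):
        _, post = growth_fit
        res = population_survival_shift(post, 0.0)
        assert np.allclose(res["samples"], 0.0)

    def test_population_shift_flat_model_is_zero(self, growth_fit):
        _, post = growth_fit
        import copy

        flat = copy.copy(post)
        flat.coefs = post.coefs.copy()
        for name in ("adult_mass", "mass_x_days"):
            flat.coefs[:, post.coef_names.index(name)] = 0.0
        res = population_survival_shift(flat, -1.0)
        assert np.allclose(res["samples"], 0.0, atol=1e-12)

    def test_extrapolation_warns(self, growth_fit):
        _, post = growth_fit
        with pytest.warns(UserWarning, match="support"):
            population_survival_shift(post, -500.0)

    def test_rhat_reported_per_coefficient(self):
        ds_caps = make_captures(
            np.full(12, 42.0), np.full(12, 0.023), np.full(12, 160.0),
            (190, 215, 240, 265),
        )
        model = GrowthSurvivalModel(
            spec=GrowthModelSpec(include_snow_interaction=False),
            mcmc=GrowthMCMC(iterations=600, burnin=200, thin=4, n_chains=2, seed=5),
        )
        model.fit(ds_caps, SNOW, make_survival(ds_caps["id"].unique()))
        summ = model.posterior_.coef_summary()
        assert summ["rhat"].notna().all()


class TestPhenology:
    def test_exact_lag_recovered(self):
        snow = pd.DataFrame(
            {"year": [1, 2, 3, 4], "snowmelt_day": [100.0, 110.0, 120.0, 130.0],
             "first_snowfall_day": [280.0] * 4}
        )
        bd = pd.DataFrame({"year": [1, 2, 3, 4],
                           "t0": [140.0, 150.0, 160.0, 170.0]})
        res = phenology_regression(bd, snow)
        assert res["lag_mean"] == pytest.approx(40.0)
        assert res["lag_se"] == pytest.approx(0.0, abs=1e-9)
        assert res["slope"] == pytest.approx(1.0)

    def test_degenerate_design_warns(self):
        snow = pd.DataFrame(
            {"year": [1, 2, 3], "snowmelt_day": [100.0] * 3,
             "first_snowfall_day": [280.0] * 3}
        )
        bd = pd.DataFrame({"year": [1, 2, 3], "t0": [140.0, 141.0, 139.0]})
        with pytest.warns(UserWarning, match="identical snowmelt"):
            res = phenology_regression(bd, snow)
        assert np.isnan(res["slope"])
        assert res["lag_mean"] == pytest.approx(40.0)

    def test_too_few_years_raise(self):
        snow = pd.DataFrame({"year": [1], "snowmelt_day": [100.0],
                             "first_snowfall_day": [280.0]})
        with pytest.raises(ValueError, match="undefined"):
            phenology_regression(pd.DataFrame({"year": [1], "t0": [140.0]}), snow)

    def test_posterior_birth_dates_are_occupied_litters(self, growth_fit):
        ds, post = growth_fit
        bd = posterior_birth_dates(post)
        assert {"mother", "year", "litter", "t0"} <= set(bd.columns)
        assert len(bd) >= ds.truth.litters.groupby(["mother", "year"]).ngroups * 0.5


class TestPosteriorPredictiveChecks:
    def test_well_specified_fit_is_calibrated(self, growth_fit):
        ds, post = growth_fit
        res = posterior_predictive_check(post, ds.captures, seed=1)
        assert 0.02 < res["ppp_mass"] < 0.98
        assert 0.02 < res["ppp_survival"] < 0.98

    def test_shifted_masses_fail_the_check(self, growth_fit):
        ds, post = growth_fit
        shifted = ds.captures.copy()
        shifted["mass"] += 10.0
        res = posterior_predictive_check(post, shifted, seed=1)
        assert res["ppp_mass"] < 0.01
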