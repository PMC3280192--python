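"""Synthetic-data generators: determinism, planted truth, closed-form pool
dynamics, growth-curve model identities, and competitive protection."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from carrierscreen import StrainCatalog
from carrierscreen._exceptions import DomainError, StagnationError
from carrierscreen.colony import PlateImage, quantify_plate
from carrierscreen.simulate import (
    SimParams,
    apply_protection,
    final_proportions,
    hill_rate,
    make_truth,
    render_plate_image,
    simulate_growth_curve,
    simulate_pool,
)

NOISELESS = dict(pixel_noise_sd=0.0, suppressor_rate=0.0, edge_boost=1.0)


class TestRender:
    def test_same_seed_bit_identical(self, catalog, test_layout):
        truth = make_truth(catalog, resistant=["can1Δ"])
        params = SimParams(rng_seed=5)
        a = render_plate_image(test_layout, truth, params, treated=True)
        b = render_plate_image(test_layout, truth, params, treated=True)
        assert np.array_equal(a.image, b.image)
        assert a.truth_sizes.equals(b.truth_sizes)

    def test_full_inhibition_leaves_empty_interior(self, catalog, test_layout):
        truth = make_truth(catalog, inhibition=1.0)
        truth.frame.loc[:, "inhibition"] = 1.0  # WT included: everything killed
        params = SimParams(rng_seed=0, **NOISELESS)
        result = render_plate_image(test_layout, truth, params, treated=True)
        assert (result.truth_sizes["true_pixels"] == 0).all()
        assert (result.image[..., 2] == params.bg_level).all()

    def test_resistant_strain_keeps_untreated_radius(self, catalog, test_layout):
        truth = make_truth(catalog, resistant=["can1Δ"], inhibition=0.9)
        params = SimParams(rng_seed=0, **NOISELESS)
        untreated = render_plate_image(test_layout, truth, params, treated=False)
        treated = render_plate_image(test_layout, truth, params, treated=True)
        for result in (untreated, treated):
            sizes = result.truth_sizes.query("strain_id == 'can1Δ'")["true_pixels"]
            assert (sizes == untreated.truth_sizes["true_pixels"].max()).all()

    def test_round_trip_counts_increase_with_radius(self, catalog, test_layout):
        """Quantifier counts on a noiseless plate equal the true disc areas
        and grow strictly with the planted growth score."""
        params = SimParams(rng_seed=1, **NOISELESS)
        scores = np.linspace(0.2, 1.0, 5)
        counts = []
        for s in scores:
            truth = make_truth(catalog, inhibition=float(1 - s))
            result = render_plate_image(test_layout, truth, params, treated=True)
            table = quantify_plate(PlateImage(result.image, result.corners), test_layout)
            joined = table.merge(result.truth_sizes, on=["row", "col"])
            assert (joined["pixel_count"] == joined["true_pixels"]).all()
            counts.append(joined["pixel_count"].median())
        assert all(b > a for a, b in zip(counts, counts[1:]))

    def test_too_small_windows_rejected(self, catalog, test_layout):
        truth = make_truth(catalog)
        with pytest.raises(Exception):
            render_plate_image(test_layout, truth, SimParams(px_per_window=3), treated=False)


def two_strain_catalog():
    return StrainCatalog.from_genes(["RES1", "SUS1"])


class TestPool:
    def test_symmetric_pool_equal_afu(self, catalog):
        truth = make_truth(catalog, inhibition=0.0)
        prof = simulate_pool(catalog, truth, SimParams(rng_seed=0), noise=False)
        assert np.allclose(prof["afu_treated"], prof["afu_treated"].iloc[0])
        assert np.allclose(prof["afu_untreated"], prof["afu_treated"])

    def test_resistant_proportion_rises_under_treatment(self):
        cat = two_strain_catalog()
        truth = make_truth(cat, resistant=["res1Δ"], inhibition=0.9)
        prof = simulate_pool(cat, truth, SimParams(rng_seed=0), noise=False).set_index("strain_id")
        assert prof.loc["res1Δ", "p_treated"] > prof.loc["res1Δ", "p_untreated"]

    def test_proportions_sum_to_one(self, catalog):
        truth = make_truth(catalog, resistant=["can1Δ"], inhibition=0.9)
        prof = simulate_pool(catalog, truth, SimParams(rng_seed=3))
        assert prof["p_untreated"].sum() == pytest.approx(1.0, abs=1e-12)
        assert prof["p_treated"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_matches_numerical_integration(self):
        """1 resistant of 100, 90% inhibition elsewhere: the stop-time
        proportions from the root solve equal direct ODE integration, and
        the resistant strain tops the treated readout."""
        cat = StrainCatalog.from_genes([f"G{i}" for i in range(100)])
        truth = make_truth(cat, resistant=["g0Δ"], inhibition=0.9)
        params = SimParams(rng_seed=0)
        prof = simulate_pool(cat, truth, params, noise=False).set_index("strain_id")

        inhib = truth.frame.set_index("strain_id").loc[prof.index, "inhibition"].to_numpy()
        mu = params.mu_wt * (1.0 - inhib)
        n = len(prof)
        n0 = np.full(n, 1.0 / n)

        def rhs(t, n):
            return mu * n

        # integrate until total biomass reaches stop_mult x inoculum
        def stop(t, n):
            return n.sum() - params.stop_mult

        stop.terminal, stop.direction = True, 1.0
        sol = solve_ivp(rhs, (0, 500), n0, events=stop, rtol=1e-11, atol=1e-14,
                        dense_output=True)
        n_final = sol.y_events[0][0]
        p_ode = n_final / n_final.sum()
        np.testing.assert_allclose(prof["p_treated"].to_numpy(), p_ode, atol=1e-6)
        assert prof["afu_treated"].idxmax() == "g0Δ"

    def test_closed_form_limit_agreement(self):
        """Stop-time proportions match n0 e^{mu t*} / sum to 1e-9."""
        mu = np.array([0.35, 0.035, 0.2])
        p = final_proportions(mu, stop_mult=100.0)
        # independent reconstruction at the implied stop time
        from carrierscreen.simulate import pool_stop_time

        t = pool_stop_time(mu, 100.0)
        expected = np.exp(mu * t) / np.exp(mu * t).sum()
        np.testing.assert_allclose(p, expected, atol=1e-9)
        assert np.exp(mu * t).sum() / 3 == pytest.approx(100.0, rel=1e-9)

    def test_treated_proportion_monotone_in_inhibition(self):
        cat = StrainCatalog.from_genes([f"G{i}" for i in range(10)])
        params = SimParams(rng_seed=0)
        previous = None
        for inhib in [0.0, 0.3, 0.6, 0.9]:
            frame = make_truth(cat, inhibition=0.5).frame.copy()
            frame.loc[frame["strain_id"] == "g0Δ", "inhibition"] = inhib
            frame.loc[:, "planted_call"] = "none"
            from carrierscreen.simulate import TruthTable

            prof = simulate_pool(cat, TruthTable(frame), params, noise=False)
            p = prof.set_index("strain_id").loc["g0Δ", "p_treated"]
            if previous is not None:
                assert p <= previous + 1e-12
            previous = p

    def test_stagnant_pool_rejected(self):
        cat = two_strain_catalog()
        truth = make_truth(cat, inhibition=1.0)
        truth.frame.loc[:, "inhibition"] = 1.0
        with pytest.raises(StagnationError):
            simulate_pool(cat, truth, SimParams(rng_seed=0))

    def test_seed_determinism(self, catalog):
        truth = make_truth(catalog, resistant=["can1Δ"])
        a = simulate_pool(catalog, truth, SimParams(rng_seed=9))
        b = simulate_pool(catalog, truth, SimParams(rng_seed=9))
        assert a.equals(b)


class TestGrowthCurveModel:
    def test_log_slope_matches_logistic_model(self):
        """Post-lag, d ln(x)/dt equals mu (1 - x/K): the generated samples
        lie on the stated logistic solution."""
        params = SimParams(rng_seed=0, lag_h=2.0, od_noise_sd=0.0)
        mu, K = 0.30, params.carrying_od
        curve = simulate_growth_curve(mu, 0.0, params)
        x = curve["od600"].to_numpy() - params.blank_od
        t = curve["time_min"].to_numpy() / 60.0
        sel = (t > 2.1) & (x < 0.8 * K)
        slopes = np.diff(np.log(x[sel])) / np.diff(t[sel])
        x_mid = np.sqrt(x[sel][:-1] * x[sel][1:])  # geometric midpoint
        expected = mu * (1 - x_mid / K)
        np.testing.assert_allclose(slopes, expected, rtol=0.01)

    def test_hill_midpoint_halves_rate(self):
        params = SimParams(rng_seed=0)
        assert hill_rate(0.4, params.ic50_uM, params.ic50_uM, params.hill_h) == pytest.approx(0.2)

    def test_ic90_concentration_gives_tenth_rate(self):
        """c = IC50 * 9^(1/h) removes 90% of the growth rate."""
        ic50, h = 10.0, 1.5
        c90 = ic50 * 9 ** (1 / h)
        assert hill_rate(1.0, c90, ic50, h) == pytest.approx(0.1, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            simulate_growth_curve(0.3, -1.0, SimParams(rng_seed=0))

    def test_startup_read_is_media_blank(self):
        params = SimParams(rng_seed=0, od_noise_sd=0.0)
        curve = simulate_growth_curve(0.3, 0.0, params)
        assert curve["od600"].iloc[0] == params.blank_od


class TestProtection:
    def test_no_competitor_identity(self):
        assert apply_protection(12.0, 0.0, 5.0) == 12.0

    def test_competitor_at_ks_halves_concentration(self):
        assert apply_protection(12.0, 5.0, 5.0) == pytest.approx(6.0)

    def test_saturating_competitor_full_protection(self):
        assert apply_protection(12.0, 1e9, 5.0) < 1e-6
        mu = hill_rate(0.35, apply_protection(30.0, 1e9, 5.0), 10.0, 2.0)
        assert mu == pytest.approx(0.35, rel=1e-6)

    def test_monotone_decreasing_in_competitor(self):
        effs = [apply_protection(30.0, c, 2.0) for c in [0, 1, 5, 20, 100]]
        assert all(b < a for a, b in zip(effs, effs[1:]))
        assert all(e <= 30.0 for e in effs)

    def test_zero_ks_rejected(self):
        with pytest.raises(DomainError):
            apply_protection(10.0, 1.0, 0.0)
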