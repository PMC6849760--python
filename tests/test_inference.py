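import math

import numpy as np
import pytest

from phytoscale.core import Community, MSTParams, community_rate
from phytoscale.errors import DataError, IdentifiabilityError
from phytoscale.inference import (
    ModelSpec,
    compare_treatment_models,
    fit_mst,
    log_likelihood,
    profile_ci,
)
from phytoscale.simulate import SimulationConfig, simulate_experiment

TRUTH = SimulationConfig().true_params_gpp


def small_communities(seed=0, n=6, treatments=("ambient", "warm")):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        masses = rng.lognormal(-10.0, 1.0, size=30)
        comm = Community(
            f"c{i}",
            treatments[i % len(treatments)],
            289.15 if i % 2 else 293.15,
            masses,
            scale_to_litre=100.0,
        )
        comm.gpp_obs = community_rate(TRUTH, comm) * math.exp(rng.normal(0, 0.2))
        comm.cr_obs = comm.gpp_obs * 0.4
        out.append(comm)
    return out


class TestLogLikelihood:
    def test_single_community_exact_prediction(self):
        comm = small_communities(n=1, seed=1)[0]
        params = MSTParams(TRUTH.ln_b_tc, TRUTH.alpha, TRUTH.activation_energy, sigma=0.5)
        comm.gpp_obs = community_rate(params, comm)
        ll = log_likelihood(params, [comm], "gpp")
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi * 0.5**2), rel=1e-12)

    def test_three_community_brute_force(self):
        comms = small_communities(n=3, seed=2)
        sigma = 0.35
        params = MSTParams(-3.0, 0.9, 0.55, sigma=sigma)
        # independent evaluation: explicit per-cell sums and Normal density
        expected = 0.0
        k = 8.62e-5
        for c in comms:
            s = sum(m**0.9 for m in c.masses) * c.scale_to_litre
            pred = math.log(s) - 3.0 + 0.55 * (1 / (k * 291.15) - 1 / (k * c.incubator_t))
            z = (math.log(c.gpp_obs) - pred) / sigma
            expected += -0.5 * math.log(2 * math.pi * sigma**2) - 0.5 * z * z
        assert log_likelihood(params, comms, "gpp") == pytest.approx(expected, rel=1e-10)

    def test_nonpositive_rate_rejected(self):
        comms = small_communities(n=2, seed=3)
        comms[0].gpp_obs = -1.0
        with pytest.raises(DataError):
            log_likelihood(TRUTH, comms, "gpp")


class TestFitMST:
    def test_noise_free_recovery(self, noise_free_communities):
        for flux, truth in (
            ("gpp", SimulationConfig().true_params_gpp),
            ("cr", SimulationConfig().true_params_cr),
        ):
            fit = fit_mst(noise_free_communities, flux, n_starts=15, seed=0, compute_ci=False)
            assert abs(fit.params["E"] - truth.activation_energy) < 1e-4
            assert abs(fit.params["alpha"] - truth.alpha) < 1e-4
            assert abs(fit.params["ln_b_tc"] - truth.ln_b_tc) < 1e-4

    def test_concentrated_matches_direct_likelihood(self, noisy_communities, noisy_gpp_fit):
        # dual route: the concentrated optimum evaluated through the plain
        # per-community Normal likelihood must reproduce the stored loglik
        params = noisy_gpp_fit.params_for()
        direct = log_likelihood(params, noisy_communities, "gpp")
        assert direct == pytest.approx(noisy_gpp_fit.loglik, rel=1e-9)

    def test_aic_definition(self, noisy_gpp_fit):
        assert noisy_gpp_fit.aic == pytest.approx(
            2 * noisy_gpp_fit.n_params - 2 * noisy_gpp_fit.loglik
        )

    def test_mass_rescaling_invariance(self, noisy_communities, noisy_gpp_fit):
        c = 7.5
        rescaled = []
        for comm in noisy_communities:
            clone = Community(
                comm.id, comm.mesocosm_treatment, comm.incubator_t,
                comm.masses * c, comm.scale_to_litre, comm.gpp_obs, comm.cr_obs,
            )
            rescaled.append(clone)
        refit = fit_mst(rescaled, "gpp", n_starts=15, seed=0, compute_ci=False)
        assert refit.params["E"] == pytest.approx(noisy_gpp_fit.params["E"], abs=1e-6)
        assert refit.params["alpha"] == pytest.approx(noisy_gpp_fit.params["alpha"], abs=1e-6)
        assert refit.params["ln_b_tc"] == pytest.approx(
            noisy_gpp_fit.params["ln_b_tc"] - noisy_gpp_fit.params["alpha"] * math.log(c),
            abs=1e-5,
        )

    def test_single_temperature_not_identifiable(self):
        comms = small_communities(n=6, seed=4)
        for c in comms:
            c.incubator_t = 291.15
        with pytest.raises(IdentifiabilityError, match="E"):
            fit_mst(comms, "gpp", n_starts=5, seed=0, compute_ci=False)

    def test_deterministic_under_seed(self, noisy_communities):
        a = fit_mst(noisy_communities, "gpp", n_starts=10, seed=5, compute_ci=False)
        b = fit_mst(noisy_communities, "gpp", n_starts=10, seed=5, compute_ci=False)
        assert a.params == b.params

    def test_gpp_less_temperature_sensitive_than_cr(self, noisy_communities):
        gpp = fit_mst(noisy_communities, "gpp", n_starts=10, seed=0, compute_ci=False)
        cr = fit_mst(noisy_communities, "cr", n_starts=10, seed=0, compute_ci=False)
        assert gpp.params["E"] < cr.params["E"]


class TestProfileCI:
    def test_brackets_estimate(self, noisy_gpp_fit):
        for name in ("E", "alpha", "ln_b_tc"):
            ci = profile_ci(noisy_gpp_fit, name, seed=0)
            assert ci.lower < noisy_gpp_fit.params[name] < ci.upper

    def test_widens_with_noise(self):
        widths = {}
        for noise in (0.15, 0.45):
            config = SimulationConfig(
                n_cells=150, noise_sd=noise, abundance_noise_sd=0.1, seed=21
            )
            comms, _ = simulate_experiment(config)
            fit = fit_mst(comms, "gpp", n_starts=10, seed=0, compute_ci=False)
            ci = profile_ci(fit, "E", seed=0)
            widths[noise] = ci.upper - ci.lower
        assert widths[0.45] > widths[0.15]

    def test_unknown_parameter_rejected(self, noisy_gpp_fit):
        with pytest.raises(DataError):
            profile_ci(noisy_gpp_fit, "nope")

    def test_fit_populates_cis(self, noisy_communities):
        fit = fit_mst(noisy_communities, "gpp", n_starts=10, seed=0, compute_ci=True)
        assert set(fit.ci) == {"E", "alpha", "ln_b_tc"}
        for name, ci in fit.ci.items():
            assert ci.lower < fit.params[name] < ci.upper


class TestModelComparison:
    def test_duplicated_communities_give_zero_statistic(self):
        base = small_communities(n=8, treatments=("ambient",), seed=6)
        mirrored = []
        for c in base:
            clone = Community(
                c.id + "_w", "warm", c.incubator_t, c.masses.copy(),
                c.scale_to_litre, c.gpp_obs, c.cr_obs,
            )
            mirrored.append(clone)
        rows, _ = compare_treatment_models(base + mirrored, "gpp", n_starts=10, seed=0)
        for row in rows:
            assert row.converged
            assert row.statistic == pytest.approx(0.0, abs=1e-6)

    def test_statistics_nonnegative(self, noisy_communities):
        rows, fits = compare_treatment_models(noisy_communities, "gpp", n_starts=10, seed=0)
        assert {r.parameter for r in rows} == {"ln_b_tc", "E", "alpha"}
        for row in rows:
            assert row.statistic >= -1e-8
            assert 0.0 <= row.p_value <= 1.0

    def test_detects_treatment_split_in_E(self):
        warm_params = MSTParams(TRUTH.ln_b_tc, TRUTH.alpha, TRUTH.activation_energy + 0.8)
        config = SimulationConfig(n_cells=150, noise_sd=0.1, seed=23)
        comms, _ = simulate_experiment(config)
        rng = np.random.default_rng(23)
        for c in comms:
            if c.mesocosm_treatment == "warm":
                c.gpp_obs = community_rate(warm_params, c) * math.exp(rng.normal(0, 0.1))
        rows, _ = compare_treatment_models(comms, "gpp", n_starts=10, seed=0)
        by_param = {r.parameter: r for r in rows}
        assert by_param["E"].p_value < 0.05
        assert by_param["E"].preferred == "split:E"

    def test_single_treatment_rejected(self):
        comms = small_communities(n=6, treatments=("ambient",), seed=7)
        with pytest.raises(DataError):
            compare_treatment_models(comms, "gpp")

    def test_split_model_spec_fits(self, noisy_communities):
        fit = fit_mst(
            noisy_communities, "gpp", ModelSpec.splitting("E"),
            n_starts=10, seed=0, compute_ci=False,
        )
        assert "E[ambient]" in fit.params and "E[warm]" in fit.params
        assert "ln_b_tc" in fit.params

    def test_unknown_split_rejected(self):
        with pytest.raises(DataError):
            ModelSpec.splitting("gamma")
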