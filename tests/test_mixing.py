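import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from isomix import (
    MixingFitConfig,
    SourceProfile,
    ValidationError,
    aggregate_sources,
    default_source_profiles,
    fit_mixing_model,
    hdr,
    log_likelihood,
    modal_probability_estimate,
    split_rhat,
    summarize_apportionment,
    tracer_redundancy_check,
)
from isomix.synth import (
    MixtureScenario,
    generate_mixture_samples,
    recovery_scenario,
)


def brute_force_loglik(x, p, sigma, sources, tracers):
    total = 0.0
    for i in range(x.shape[0]):
        for j, t in enumerate(tracers):
            m = sum(pk * (s.means[t] + s.offsets.get(t, 0.0))
                    for pk, s in zip(p, sources))
            v = sum(pk ** 2 * s.sds[t] ** 2 for pk, s in zip(p, sources))
            total += norm.logpdf(x[i, j], m, math.sqrt(v + sigma[j] ** 2))
    return total


class TestLogLikelihood:
    def test_single_source_at_mean_is_standard_normal_density(self):
        src = [SourceProfile(name="s", means={"t": 5.0}, sds={"t": 0.0})]
        ll = log_likelihood(np.array([[5.0]]), [1.0], [1.0], src, tracers=("t",))
        assert ll == pytest.approx(math.log(1.0 / math.sqrt(2 * math.pi)), abs=1e-12)

    def test_symmetric_under_source_swap(self):
        a = SourceProfile(name="a", means={"t": 3.0}, sds={"t": 1.0})
        b = SourceProfile(name="b", means={"t": 3.0}, sds={"t": 1.0})
        x = np.array([[2.0], [4.0]])
        assert log_likelihood(x, [0.3, 0.7], [0.5], [a, b], ("t",)) == pytest.approx(
            log_likelihood(x, [0.7, 0.3], [0.5], [a, b], ("t",)), abs=1e-12
        )

    def test_matches_brute_force_on_random_instances(self, rng):
        tracers = ("d15N", "D17O")
        for _ in range(20):
            k = rng.integers(1, 5)
            sources = [
                SourceProfile(
                    name=f"s{i}",
                    means={t: float(rng.normal(0, 10)) for t in tracers},
                    sds={t: float(abs(rng.normal(0, 3))) for t in tracers},
                    offsets={"d15N": float(rng.normal(0, 1))},
                )
                for i in range(k)
            ]
            p = rng.dirichlet(np.ones(k))
            sigma = np.abs(rng.normal(1, 0.3, 2)) + 0.1
            x = rng.normal(size=(3, 2))
            assert log_likelihood(x, p, sigma, sources, tracers) == pytest.approx(
                brute_force_loglik(x, p, sigma, sources, tracers), abs=1e-9
            )

    def test_missing_tracer_value_names_sample(self, default_sources):
        df = pd.DataFrame(
            {"sample_id": ["ok", "bad"], "d15N": [1.0, 2.0], "D17O": [3.0, np.nan]}
        )
        with pytest.raises(ValidationError, match="bad"):
            log_likelihood(df, [0.25] * 4, [1.0, 1.0], default_sources)

    def test_off_simplex_rejected(self, default_sources):
        with pytest.raises(ValidationError):
            log_likelihood(
                np.zeros((1, 2)), [0.5, 0.5, 0.5, 0.5], [1, 1], default_sources
            )


class TestFit:
    def test_posterior_mean_matches_grid_integration(self, two_sources):
        # one sample at 25 between sources at 0 and 100: fine-grid oracle
        grid = np.linspace(0.0, 1.0, 20001)
        var = grid ** 2 * 0.01 + (1 - grid) ** 2 * 0.01 + 1.0
        dens = np.exp(-((25.0 - 100.0 * grid) ** 2) / (2 * var)) / np.sqrt(var)
        oracle = float(np.trapezoid(dens * grid, grid) / np.trapezoid(dens, grid))
        assert oracle == pytest.approx(0.25, abs=0.01)

        cfg = MixingFitConfig(
            tracers=("t",), iterations=60_000, burn_in=10_000, seed=11,
            sigma_fixed=(1.0,),
        )
        draws = fit_mixing_model(np.array([[25.0]]), two_sources, cfg)
        assert draws.p[:, 1].mean() == pytest.approx(oracle, abs=0.02)

    def test_identical_sources_give_uniform_posterior(self):
        sources = [
            SourceProfile(name=f"s{i}", means={"t": 1.0}, sds={"t": 1.0})
            for i in range(3)
        ]
        cfg = MixingFitConfig(tracers=("t",), iterations=60_000, burn_in=10_000, seed=2)
        draws = fit_mixing_model(np.array([[1.0], [1.2]]), sources, cfg)
        assert np.allclose(draws.p.mean(axis=0), 1 / 3, atol=0.03)

    def test_deterministic_under_seed(self, default_sources):
        x = pd.DataFrame({"d15N": [0.0, 1.0], "D17O": [5.0, 6.0]})
        cfg = MixingFitConfig(iterations=5_000, burn_in=1_000, seed=42)
        d1 = fit_mixing_model(x, default_sources, cfg)
        d2 = fit_mixing_model(x, default_sources, cfg)
        assert np.array_equal(d1.p, d2.p) and np.array_equal(d1.sigma, d2.sigma)

    def test_draw_count_and_acceptance(self, default_sources):
        x = pd.DataFrame({"d15N": [0.0, 1.0], "D17O": [5.0, 6.0]})
        cfg = MixingFitConfig(iterations=21_000, burn_in=1_000, thin=2, seed=0)
        d = fit_mixing_model(x, default_sources, cfg)
        assert d.n_draws == 10_000
        assert 0.0 < d.acceptance_rate < 1.0

    def test_draws_lie_on_simplex(self, default_sources):
        x = pd.DataFrame({"d15N": [0.0], "D17O": [5.0]})
        cfg = MixingFitConfig(iterations=10_000, burn_in=2_000, seed=1)
        d = fit_mixing_model(x, default_sources, cfg)
        assert np.all(d.p >= 0) and np.all(d.p <= 1)
        assert np.allclose(d.p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(d.sigma > 0)

    def test_prior_recovery_with_likelihood_off(self, default_sources):
        x = pd.DataFrame({"d15N": [0.0], "D17O": [0.0]})
        cfg = MixingFitConfig(
            iterations=80_000, burn_in=10_000, seed=3, prior_only=True
        )
        d = fit_mixing_model(x, default_sources, cfg)
        assert np.allclose(d.p.mean(axis=0), 0.25, atol=0.02)

    def test_posterior_predictive_tracks_sample_mean(self, default_sources):
        sc = recovery_scenario("inflow", seed=9)
        samples = generate_mixture_samples(sc)
        cfg = MixingFitConfig(iterations=40_000, burn_in=5_000, seed=9)
        d = fit_mixing_model(samples, default_sources, cfg)
        p_bar = d.p.mean(axis=0)
        for j, t in enumerate(("d15N", "D17O")):
            mu = np.array([s.means[t] for s in default_sources])
            sd = np.array([s.sds[t] for s in default_sources])
            pooled = math.sqrt(float((p_bar ** 2 * sd ** 2).sum()) +
                               sc.residual_sds[t] ** 2)
            pred = float(p_bar @ mu)
            assert abs(pred - samples[t].mean()) <= 3 * pooled / math.sqrt(sc.n)

    def test_parameter_recovery_averaged_over_seeds(self):
        # informative, fully identified configuration (two tracers pin three
        # sources), n=17: mean |MPE/100 - p_true| <= 0.08 per source over 5 seeds
        d15n = (-10.0, 0.0, 12.0)
        d17o = (25.0, 0.0, 8.0)
        sources = [
            SourceProfile(name=f"s{i}", means={"d15N": d15n[i], "D17O": d17o[i]},
                          sds={"d15N": 1.0, "D17O": 1.0})
            for i in range(3)
        ]
        p_true = np.array([0.23, 0.62, 0.15])
        errs = np.zeros(3)
        n_seeds = 5
        for seed in range(1, n_seeds + 1):
            sc = MixtureScenario(
                p_true=p_true, sources=sources,
                residual_sds={"d15N": 0.5, "D17O": 1.0}, n=17, seed=seed,
            )
            cfg = MixingFitConfig(iterations=50_000, burn_in=8_000, seed=seed)
            d = fit_mixing_model(generate_mixture_samples(sc), sources, cfg)
            summ = summarize_apportionment(d)
            mpe = np.array([summ.mpe[s.name] for s in sources]) / 100.0
            errs += np.abs(mpe - p_true)
        assert np.all(errs / n_seeds <= 0.08)

    def test_nonfinite_initialization_reports(self):
        # zero source spread and a vanishing fixed sigma: the residual term
        # overflows to -inf at the starting point
        src = [SourceProfile(name="s", means={"t": 0.0}, sds={"t": 0.0})]
        cfg = MixingFitConfig(
            tracers=("t",), iterations=2_000, burn_in=500,
            sigma_fixed=(1e-160,),
        )
        with pytest.raises(ValidationError, match="initialization"):
            fit_mixing_model(np.array([[5.0]]), src, cfg)


class TestMode:
    def test_degenerate_draws(self):
        assert modal_probability_estimate(np.full(500, 0.4)) == pytest.approx(40.0)

    @pytest.mark.parametrize("a, b, mode", [(5, 2, 80.0), (2, 5, 20.0)])
    def test_beta_modes(self, rng, a, b, mode):
        draws = rng.beta(a, b, 100_000)
        assert modal_probability_estimate(draws) == pytest.approx(mode, abs=2.0)

    def test_too_few_draws(self):
        with pytest.raises(ValidationError):
            modal_probability_estimate(np.linspace(0, 1, 99))


class TestHDR:
    def test_standard_normal_95(self, rng):
        x = rng.standard_normal(1_000_000)
        lo, hi = hdr(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_nesting(self, rng):
        for draws in (rng.standard_normal(5_000),
                      rng.beta(2, 8, 5_000),
                      np.concatenate([rng.normal(-3, 0.5, 2_500),
                                      rng.normal(3, 0.5, 2_500)])):
            l50, h50 = hdr(draws, 0.50)
            l75, h75 = hdr(draws, 0.75)
            l95, h95 = hdr(draws, 0.95)
            assert l95 <= l75 <= l50 and h50 <= h75 <= h95

    def test_point_mass(self):
        lo, hi = hdr(np.full(200, 3.14), 0.95)
        assert lo == hi == pytest.approx(3.14)

    def test_bad_level(self, rng):
        with pytest.raises(ValidationError):
            hdr(rng.standard_normal(500), 1.5)


class TestSummaries:
    def test_two_source_mpes_are_complementary(self, two_sources):
        cfg = MixingFitConfig(tracers=("t",), iterations=40_000, burn_in=5_000,
                              seed=4, sigma_fixed=(1.0,))
        d = fit_mixing_model(np.array([[30.0], [32.0]]), two_sources, cfg)
        summ = summarize_apportionment(d)
        assert sum(summ.mpe.values()) == pytest.approx(100.0, abs=5.0)

    def test_summary_schema_and_invariants(self, default_sources):
        sc = recovery_scenario("inflow", seed=2)
        cfg = MixingFitConfig(iterations=20_000, burn_in=4_000, seed=2)
        d = fit_mixing_model(generate_mixture_samples(sc), default_sources, cfg)
        summ = summarize_apportionment(d)
        df = summ.to_frame()
        assert list(df.columns) == [
            "source", "MPE", "hdr50_low", "hdr50_high",
            "hdr75_low", "hdr75_high", "hdr95_low", "hdr95_high",
        ]
        assert len(df) == 4
        for name in summ.source_names:
            lo95, hi95 = summ.hdr_bounds[name][0.95]
            assert 0.0 <= lo95 <= hi95 <= 100.0
            assert lo95 <= summ.mpe[name] <= hi95  # MPE inside its 95% HDR
            lo50, hi50 = summ.hdr_bounds[name][0.50]
            lo75, hi75 = summ.hdr_bounds[name][0.75]
            assert lo95 <= lo75 <= lo50 and hi50 <= hi75 <= hi95


class TestAggregate:
    def test_identical_sources_unchanged(self):
        a = SourceProfile(name="a", means={"t": 3.0}, sds={"t": 2.0})
        b = SourceProfile(name="b", means={"t": 3.0}, sds={"t": 2.0})
        agg = aggregate_sources(a, b, (0.3, 0.7))
        assert agg.means["t"] == pytest.approx(3.0)
        assert agg.sds["t"] == pytest.approx(2.0)

    def test_mixture_moments(self):
        a = SourceProfile(name="a", means={"t": 0.0}, sds={"t": 0.0})
        b = SourceProfile(name="b", means={"t": 10.0}, sds={"t": 0.0})
        agg = aggregate_sources(a, b, (0.5, 0.5))
        assert agg.means["t"] == pytest.approx(5.0)
        assert agg.sds["t"] == pytest.approx(5.0)

    def test_sd_grows_with_mean_separation(self):
        sds = []
        for delta in (0.0, 5.0, 10.0, 20.0):
            a = SourceProfile(name="a", means={"t": 0.0}, sds={"t": 1.0})
            b = SourceProfile(name="b", means={"t": delta}, sds={"t": 1.0})
            sds.append(aggregate_sources(a, b, (0.4, 0.6)).sds["t"])
        assert all(x < y for x, y in zip(sds, sds[1:]))

    def test_tracer_mismatch(self):
        a = SourceProfile(name="a", means={"t": 0.0}, sds={"t": 1.0})
        b = SourceProfile(name="b", means={"u": 0.0}, sds={"u": 1.0})
        with pytest.raises(ValidationError):
            aggregate_sources(a, b, (0.5, 0.5))

    def test_moments_match_simulation(self, rng):
        a = SourceProfile(name="a", means={"t": -2.0}, sds={"t": 1.5})
        b = SourceProfile(name="b", means={"t": 6.0}, sds={"t": 0.5})
        agg = aggregate_sources(a, b, (0.25, 0.75))
        pick = rng.random(200_000) < 0.25
        draws = np.where(pick, rng.normal(-2.0, 1.5, 200_000),
                         rng.normal(6.0, 0.5, 200_000))
        assert agg.means["t"] == pytest.approx(draws.mean(), abs=0.02)
        assert agg.sds["t"] == pytest.approx(draws.std(), abs=0.02)


class TestRedundancy:
    def test_collinear(self):
        df = pd.DataFrame({"d18O": [0.0, 10.0, 20.0], "D17O": [1.0, 6.0, 11.0]})
        r2, rec = tracer_redundancy_check(df)
        assert r2 == pytest.approx(1.0)
        assert rec == "drop d18O"

    def test_independent(self, rng):
        df = pd.DataFrame(
            {"d18O": rng.normal(size=200), "D17O": rng.normal(size=200)}
        )
        r2, rec = tracer_redundancy_check(df)
        assert r2 < 0.1
        assert rec == "keep d18O"

    def test_too_few_pairs(self):
        df = pd.DataFrame({"d18O": [1.0, 2.0], "D17O": [1.0, np.nan]})
        with pytest.raises(ValidationError):
            tracer_redundancy_check(df)


class TestConvergenceDiagnostic:
    def test_split_rhat_matches_arviz(self, rng):
        az = pytest.importorskip("arviz")
        chains = rng.standard_normal((4, 2000)) + np.array([[0], [0.1], [0], [0.05]])
        mine = split_rhat(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains), method="split")["x"])
        assert mine == pytest.approx(theirs, abs=0.01)

    def test_flags_disjoint_chains(self, rng):
        chains = rng.standard_normal((4, 1000)) + np.array([[0], [0], [5], [5]])
        assert split_rhat(chains) > 1.5
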