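import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sbhbm.cohort import DesignMatrix
from sbhbm.hier_model import (
    ModelError,
    ParameterState,
    PriorConfig,
    SamplerConfig,
    convergence_diagnostics,
    half_cauchy_logpdf,
    hpdi,
    log_likelihood,
    log_posterior,
    log_prior,
    prior_only_design,
    sample_posterior,
    summarize_posterior,
)

LOG_2PI = math.log(2 * math.pi)


def random_instance(rng, n=10, R=4, G=2, K=2, M=2):
    net = rng.integers(0, M, size=R)
    net[:M] = np.arange(M)  # every network present
    design = DesignMatrix(
        X=rng.standard_normal((n, R)),
        y=rng.standard_normal(n),
        C=rng.standard_normal((n, K)),
        g=np.concatenate([np.arange(G), rng.integers(0, G, size=n - G)]),
        social_index="household",
        region_names=[f"r{j}" for j in range(R)],
        network_index=net,
        n_groups=G,
    )
    state = ParameterState(
        region_betas=rng.standard_normal((R, G)),
        network_betas=rng.standard_normal((M, G)),
        network_spreads=np.abs(rng.standard_normal((M, G))) + 0.1,
        network_scale=np.abs(rng.standard_normal(G)) + 0.1,
        confound_betas=rng.standard_normal(K),
        noise_scale=float(np.abs(rng.standard_normal())) + 0.1,
    )
    return design, state


def oracle_log_likelihood(state, design):
    total = 0.0
    for i in range(design.n):
        mu = 0.0
        for j in range(design.n_regions):
            mu += design.X[i, j] * state.region_betas[j, design.g[i]]
        for k in range(design.n_confounds):
            mu += design.C[i, k] * state.confound_betas[k]
        total += stats.norm.logpdf(design.y[i], loc=mu, scale=state.noise_scale)
    return total


def oracle_log_prior(state, priors, network_index):
    def hc(x, s):
        return math.log(2.0) + stats.cauchy.logpdf(x, scale=s)

    total = hc(state.noise_scale, priors.noise_scale_prior)
    M, G = state.network_betas.shape
    for g in range(G):
        total += hc(state.network_scale[g], priors.network_beta_scale_prior)
        for m in range(M):
            total += stats.norm.logpdf(state.network_betas[m, g], scale=state.network_scale[g])
            total += hc(state.network_spreads[m, g], priors.region_spread_prior)
    for j, m in enumerate(network_index):
        for g in range(G):
            total += stats.norm.logpdf(
                state.region_betas[j, g],
                loc=state.network_betas[m, g],
                scale=state.network_spreads[m, g],
            )
    for k in range(len(state.confound_betas)):
        total += stats.norm.logpdf(state.confound_betas[k], scale=priors.confound_beta_prior_sd)
    return total


def test_log_likelihood_standard_normal_cases():
    design = DesignMatrix(
        X=np.zeros((3, 2)), y=np.zeros(3), C=np.zeros((3, 0)), g=np.zeros(3, int),
        social_index="household", region_names=["a", "b"], network_index=[0, 0], n_groups=1,
    )
    state = ParameterState(
        region_betas=np.zeros((2, 1)), network_betas=np.zeros((1, 1)),
        network_spreads=np.ones((1, 1)), network_scale=np.ones(1),
        confound_betas=np.zeros(0), noise_scale=1.0,
    )
    assert log_likelihood(state, design) == pytest.approx(-1.5 * LOG_2PI)
    one = DesignMatrix(
        X=np.array([[2.0]]), y=np.array([1.0]), C=np.zeros((1, 0)), g=[0],
        social_index="household", region_names=["a"], network_index=[0], n_groups=1,
    )
    st1 = ParameterState(
        region_betas=np.array([[0.5]]), network_betas=np.zeros((1, 1)),
        network_spreads=np.ones((1, 1)), network_scale=np.ones(1),
        confound_betas=np.zeros(0), noise_scale=1.0,
    )
    # mu = 2 * 0.5 = y, so the density is the standard normal at its mode
    assert log_likelihood(st1, one) == pytest.approx(-0.5 * LOG_2PI)


def test_half_cauchy_closed_form():
    assert half_cauchy_logpdf(1.0) == pytest.approx(-math.log(math.pi))
    assert half_cauchy_logpdf(-0.3) == -np.inf


def test_log_density_oracle_equivalence():
    rng = np.random.default_rng(10)
    priors = PriorConfig()
    for _ in range(8):
        R = int(rng.integers(2, 37))
        M = min(4, R)
        design, state = random_instance(rng, n=10, R=R, G=int(rng.integers(2, 5)), M=M)
        assert log_likelihood(state, design) == pytest.approx(
            oracle_log_likelihood(state, design), abs=1e-10
        )
        assert log_prior(state, priors, design.network_index) == pytest.approx(
            oracle_log_prior(state, priors, design.network_index), abs=1e-10
        )
        assert log_posterior(state, design, priors) == pytest.approx(
            oracle_log_likelihood(state, design)
            + oracle_log_prior(state, priors, design.network_index),
            abs=1e-10,
        )


def test_log_posterior_one_observation_at_mode_shift():
    """Appending an observation with mu = y and sigma = 1 adds exactly -ln(2pi)/2."""
    rng = np.random.default_rng(3)
    design, state = random_instance(rng, n=6, R=3, G=2, M=2)
    state.noise_scale = 1.0
    mu_new = float(
        np.array([1.0, -0.5, 2.0]) @ state.region_betas[:, 1]
        + np.array([0.3, -0.2]) @ state.confound_betas
    )
    bigger = DesignMatrix(
        X=np.vstack([design.X, [1.0, -0.5, 2.0]]),
        y=np.append(design.y, mu_new),
        C=np.vstack([design.C, [0.3, -0.2]]),
        g=np.append(design.g, 1),
        social_index="household",
        region_names=design.region_names,
        network_index=design.network_index,
        n_groups=2,
    )
    priors = PriorConfig()
    assert log_posterior(state, bigger, priors) - log_posterior(state, design, priors) == pytest.approx(
        -0.5 * LOG_2PI, abs=1e-12
    )


def test_invalid_states_rejected():
    rng = np.random.default_rng(0)
    design, state = random_instance(rng)
    state.noise_scale = -1.0
    with pytest.raises(ModelError):
        log_likelihood(state, design)
    with pytest.raises(ModelError):
        PriorConfig(noise_scale_prior=0.0)


def test_sampler_seed_determinism():
    rng = np.random.default_rng(1)
    design, _ = random_instance(rng, n=40, R=4, G=2, M=2)
    cfg = SamplerConfig(n_draws=80, burn_in=30, chains=2, seed=5)
    d1 = sample_posterior(design, PriorConfig(), cfg)
    d2 = sample_posterior(design, PriorConfig(), cfg)
    assert np.array_equal(d1.region_betas, d2.region_betas)
    assert np.array_equal(d1.noise_scale, d2.noise_scale)
    d3 = sample_posterior(design, PriorConfig(), SamplerConfig(n_draws=80, burn_in=30, chains=2, seed=6))
    assert not np.array_equal(d1.region_betas, d3.region_betas)


def test_sampler_rejects_empty_group():
    rng = np.random.default_rng(1)
    design, _ = random_instance(rng, n=30, R=3, G=2, M=2)
    design.g[:] = 0  # group 1 empty
    with pytest.raises(ModelError, match="non-empty"):
        sample_posterior(design, PriorConfig(), SamplerConfig(n_draws=20, burn_in=10))


def test_hpdi_examples():
    assert hpdi([0.5, 0.5, 0.5]) == (0.5, 0.5)
    assert hpdi(np.arange(1, 101), 0.95) == (1.0, 95.0)
    q = (np.arange(10_001) + 0.5) / 10_001
    samples = stats.norm.ppf(q)
    lo, hi = hpdi(samples, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.01) and hi == pytest.approx(1.96, abs=0.01)
    with pytest.raises(ModelError):
        hpdi([1.0])


def oracle_hpdi(samples, prob):
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    m = int(math.ceil(prob * n))
    if m >= n:
        return float(s[0]), float(s[-1])
    best_w, best_i = None, None
    for i in range(n - m + 1):
        w = s[i + m - 1] - s[i]
        if best_w is None or w < best_w:  # strict <: earliest window wins ties
            best_w, best_i = w, i
    return float(s[best_i]), float(s[best_i + m - 1])


@settings(derandomize=True, max_examples=120)
@given(
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=200),
    st.sampled_from([0.5, 0.8, 0.9, 0.95]),
)
def test_hpdi_matches_exhaustive_window_oracle(values, prob):
    assert hpdi(values, prob) == oracle_hpdi(values, prob)


def test_summarize_posterior_bookkeeping(default_atlas):
    design = prior_only_design()
    draws = sample_posterior(design, PriorConfig(), SamplerConfig(n_draws=60, burn_in=20, chains=2, seed=0))
    summary = summarize_posterior(draws, default_atlas)
    counts = summary["parameter_type"].value_counts()
    assert counts["region"] == 36 * 4
    assert counts["network"] == 4 * 4
    assert counts["confound"] == 2
    assert counts["noise"] == 1
    assert (summary["hpdi_lower"] <= summary["hpdi_upper"]).all()
    # means match an independent streaming oracle
    rb = draws.flat("region_betas")
    stream = 0.0
    for s in range(rb.shape[0]):
        stream += (rb[s, 0, 0] - stream) / (s + 1)
    row = summary[(summary["parameter_type"] == "region")].iloc[0]
    assert row["posterior_mean"] == pytest.approx(stream, abs=1e-12)


def test_summarize_constant_draws(default_atlas):
    design = prior_only_design()
    draws = sample_posterior(design, PriorConfig(), SamplerConfig(n_draws=30, burn_in=10, chains=2, seed=0))
    draws.region_betas[:] = 0.7
    summary = summarize_posterior(draws, default_atlas)
    region = summary[summary["parameter_type"] == "region"]
    assert (region["posterior_mean"] == 0.7).all()
    assert (region["hpdi_lower"] == 0.7).all() and (region["hpdi_upper"] == 0.7).all()


def test_convergence_diagnostics_flags_shifted_chain():
    rng = np.random.default_rng(8)
    S = 600
    noise = rng.standard_normal((1, S))
    good = np.concatenate([noise, noise], axis=0)  # identical chains
    shifted = np.concatenate([noise, noise + 10.0], axis=0)

    def wrap(chains):
        design = prior_only_design(n_regions=1, network_index=[0], n_groups=1, n_confounds=0)
        draws = sample_posterior(design, PriorConfig(), SamplerConfig(n_draws=S + 10, burn_in=10, chains=2, seed=0))
        draws.region_betas = chains[:, :, None, None]
        draws.noise_scale = np.abs(chains) + 1.0
        return draws

    table_good = convergence_diagnostics(wrap(good))
    r_good = table_good.loc[table_good["parameter"] == "region_betas[0,0]", "rhat"].iloc[0]
    assert r_good == pytest.approx(1.0, abs=0.02)
    ess = table_good.loc[table_good["parameter"] == "region_betas[0,0]", "ess"].iloc[0]
    assert ess > 0.5 * 2 * S  # white noise: high effective sample size

    table_bad = convergence_diagnostics(wrap(shifted))
    r_bad = table_bad.loc[table_bad["parameter"] == "region_betas[0,0]", "rhat"].iloc[0]
    assert r_bad > 1.05
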