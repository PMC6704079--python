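"""Welch comparisons and constant-turnover flux-ratio inference."""

import warnings

import numpy as np
import pytest
from scipy.special import betainc

from prenylflux.compare import (
    GroupSummary,
    bootstrap_flux_ratio_sd,
    compare_labeling_dynamics,
    flux_ratio,
    welch_test,
    welch_test_samples,
)
from prenylflux.correction import correct_table
from prenylflux.kinetics import fit_table
from prenylflux.simulate import (
    SimulationConfig,
    apply_measurement_layer,
    strain_config,
    simulate_labeling,
)

GGPP_WT = GroupSummary(1.4, 0.1, 3)
GGPP_S037 = GroupSummary(12.8, 2.0, 3)
GGPP_S023 = GroupSummary(8.5, 0.7, 3)


def t_sf_oracle(t_abs: float, df: float) -> float:
    """Independent survival function of the central t distribution via the
    regularized incomplete beta function."""
    return 0.5 * betainc(df / 2.0, 0.5, df / (df + t_abs**2))


def test_welch_from_printed_ggpp_summaries_reproduces_p_0_010():
    result = welch_test(GGPP_WT, GGPP_S037)
    oracle_p = 2 * t_sf_oracle(abs(result.t), result.df)
    assert result.p_value == pytest.approx(oracle_p, abs=1e-12)
    assert round(result.p_value, 3) == 0.010


def test_welch_engineered_strain_pair_is_borderline():
    result = welch_test(GGPP_S037, GGPP_S023)
    oracle_p = 2 * t_sf_oracle(abs(result.t), result.df)
    assert result.p_value == pytest.approx(oracle_p, abs=1e-12)
    # published rounding of the summaries gives ~0.056; exact summaries 0.052
    assert result.p_value == pytest.approx(0.056, abs=0.005)


def test_welch_identical_groups():
    g = GroupSummary(5.0, 1.0, 3)
    result = welch_test(g, g)
    assert result.t == 0.0
    assert result.p_value == 1.0


def test_welch_symmetric_up_to_sign():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = GroupSummary(rng.uniform(1, 10), rng.uniform(0.1, 2), int(rng.integers(2, 6)))
        b = GroupSummary(rng.uniform(1, 10), rng.uniform(0.1, 2), int(rng.integers(2, 6)))
        ab, ba = welch_test(a, b), welch_test(b, a)
        assert ab.t == pytest.approx(-ba.t, abs=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)
        assert ab.df == pytest.approx(ba.df, abs=1e-12)


def test_welch_degenerate_inputs_rejected():
    with pytest.raises(ValueError, match="n >= 2"):
        welch_test(GroupSummary(1.0, 0.1, 1), GGPP_WT)
    with pytest.raises(ValueError, match="zero variance"):
        welch_test(GroupSummary(1.0, 0.0, 3), GroupSummary(2.0, 0.0, 3))


def test_flux_ratio_from_printed_pools():
    result = flux_ratio(GGPP_S037, GGPP_WT)
    assert result.ratio == pytest.approx(12.8 / 1.4, abs=1e-12)
    # delta method: 9.14 * sqrt((2/12.8)^2 + (0.1/1.4)^2)
    assert result.sd == pytest.approx(9.1428 * np.sqrt((2 / 12.8) ** 2 + (0.1 / 1.4) ** 2),
                                      abs=1e-3)
    assert result.sd == pytest.approx(1.6, abs=0.05)


def test_flux_ratio_reciprocal_and_identity():
    ab = flux_ratio(GGPP_S037, GGPP_WT)
    ba = flux_ratio(GGPP_WT, GGPP_S037)
    assert ab.ratio == pytest.approx(1.0 / ba.ratio, abs=1e-12)
    same = flux_ratio(GGPP_WT, GGPP_WT)
    assert same.ratio == 1.0 and same.sd > 0


def test_flux_ratio_turnover_adjustment():
    equal_t50 = flux_ratio(GGPP_S037, GGPP_WT, t50_a=15.0, t50_b=15.0)
    assert equal_t50.ratio == pytest.approx(12.8 / 1.4, abs=1e-12)
    slower_a = flux_ratio(GGPP_S037, GGPP_WT, t50_a=30.0, t50_b=15.0)
    assert slower_a.ratio == pytest.approx(12.8 / 1.4 / 2, abs=1e-12)
    with pytest.raises(ValueError, match="both half-times"):
        flux_ratio(GGPP_S037, GGPP_WT, t50_a=15.0)


def test_bootstrap_sd_agrees_with_delta_method_at_small_cv():
    a, b = GroupSummary(10.0, 0.3, 3), GroupSummary(5.0, 0.2, 3)
    delta = flux_ratio(a, b).sd
    boot = bootstrap_flux_ratio_sd(a, b, n_boot=200_000, rng=np.random.default_rng(0))
    assert boot == pytest.approx(delta, rel=0.05)


def test_identical_half_time_sets_not_significant():
    t50s = {"GGPP": [14.0, 16.0], "FPP": [12.0, 13.0]}
    table = compare_labeling_dynamics(t50s, {k: list(v) for k, v in t50s.items()})
    assert (table["p_value"] == 1.0).all()
    assert table["not_significant"].all()


def test_too_few_replicates_rejected():
    with pytest.raises(ValueError, match=">= 2"):
        compare_labeling_dynamics({"GGPP": [14.0]}, {"GGPP": [15.0, 16.0]})


def _replicate_t50s(config):
    states = simulate_labeling(config)
    raw = apply_measurement_layer(states, config)
    _, enrichment = correct_table(raw, config.natural_13c_abundance, config.tracer_purity)
    fits = fit_table(enrichment)
    ok = fits[~fits["degenerate"] & fits["t50_min"].notna()]
    return {m: g["t50_min"].tolist() for m, g in ok.groupby("metabolite")}


def test_proportional_strains_show_indistinguishable_dynamics(pathway):
    """Pools and flux scaled together (constant turnover): most per-pool
    Welch tests on replicate half-times stay above p = 0.10, as for a true
    null (CV 5%, n = 2)."""
    p_values = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(15):
            a = _replicate_t50s(
                strain_config("WT", pathway=pathway, noise_cv=0.05, replicates=2,
                                  rng_seed=seed)
            )
            b = _replicate_t50s(
                strain_config("S037", pathway=pathway, noise_cv=0.05, replicates=2,
                                  rng_seed=1000 + seed)
            )
            table = compare_labeling_dynamics(a, b)
            p_values.extend(table["p_value"].tolist())
    assert np.mean(np.asarray(p_values) > 0.10) >= 0.75


def test_pool_increase_at_fixed_flux_detected(pathway):
    """Positive control: pools x9 at unchanged flux slows labeling enough
    that the half-time difference is significant in >=90% of seeds."""
    base = strain_config("WT", pathway=pathway)
    detected = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(10):
            slow_cfg = SimulationConfig(
                pathway=pathway,
                pool_sizes={k: 9 * v for k, v in base.pool_sizes.items()},
                pathway_flux=base.pathway_flux,
                noise_cv=0.05,
                replicates=2,
                rng_seed=2000 + seed,
            )
            a = _replicate_t50s(
                strain_config("WT", pathway=pathway, noise_cv=0.05, replicates=2,
                                  rng_seed=3000 + seed)
            )
            b = _replicate_t50s(slow_cfg)
            table = compare_labeling_dynamics(a, b, alpha=0.05)
            detected.append((table["p_value"] < 0.05).all())
    assert np.mean(detected) >= 0.9
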