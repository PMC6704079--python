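"""Labeling simulator, carbon-loss operator and measurement layer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prenylflux.correction import (
    binomial_pattern,
    build_correction_model,
    correct_spectrum,
    mean_enrichment,
)
from prenylflux.pathway import (
    ElementalFormula,
    MetaboliteSpec,
    PathwaySpec,
    Pool,
    Reaction,
)
from prenylflux.simulate import (
    SimulationConfig,
    apply_measurement_layer,
    carbon_loss_operator,
    make_calibration_series,
    strain_config,
    simulate_labeling,
    simulate_to_steady_state,
)


@pytest.mark.parametrize(
    "dist,expected",
    [
        ([0, 0, 1], [0, 1]),  # fully labeled C2: either carbon lost keeps one label
        ([1, 0, 0, 0], [1, 0, 0]),  # unlabeled stays unlabeled
        ([0, 1, 0], [0.5, 0.5]),  # enumerate the two equally likely removals
    ],
)
def test_carbon_loss_examples(dist, expected):
    np.testing.assert_allclose(carbon_loss_operator(np.array(dist, float)), expected, atol=1e-12)


def test_carbon_loss_requires_a_carbon():
    with pytest.raises(ValueError):
        carbon_loss_operator(np.array([1.0]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(raw=st.lists(st.floats(0.0, 1.0), min_size=4, max_size=7).filter(lambda v: sum(v) > 0.05))
def test_carbon_loss_removes_labels_proportionally(raw):
    dist = np.array(raw) / np.sum(raw)
    n = len(dist) - 1
    out = carbon_loss_operator(dist)
    mean_before = np.arange(n + 1) @ dist
    mean_after = np.arange(n) @ out
    # a uniformly chosen carbon carries the pool-average label
    assert mean_after == pytest.approx(mean_before * (n - 1) / n, abs=1e-9)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_initial_state_is_natural_abundance(wt_noiseless_states):
    config, states = wt_noiseless_states
    t0 = states[0]
    assert t0.time_min == 0.0
    for pool in config.pathway.pools:
        expected = binomial_pattern(pool.n_carbons, config.natural_13c_abundance)
        np.testing.assert_allclose(
            t0.distributions[pool.name].fractions, expected, atol=1e-9
        )


def test_steady_state_enrichment_reaches_tracer_purity(pathway):
    config = strain_config("WT", pathway=pathway, noise_cv=0.0, replicates=1)
    state = simulate_to_steady_state(config)
    for pool in pathway.pools:
        assert mean_enrichment(state.distributions[pool.name]) == pytest.approx(
            config.tracer_purity, abs=1e-3
        )


def _single_pool_pathway():
    return PathwaySpec(
        metabolites=(MetaboliteSpec("X", ElementalFormula.from_string("CH4")),),
        pools=(Pool("X", 1, ("X",)),),
        reactions=(Reaction("source_feed", "X", unit_carbons=1, n_units=1),),
    )


def test_single_pool_matches_analytic_solution():
    """One pool fed by a 1-carbon source: E(t) = p*(1 - exp(-t/tau)) + baseline decay."""
    tau = 2.0
    purity = 0.99
    config = SimulationConfig(
        pathway=_single_pool_pathway(),
        pool_sizes={"X": tau},
        pathway_flux=1.0,
        tracer_purity=purity,
        natural_13c_abundance=1e-7,  # negligible baseline isolates the closed form
        timepoints=(0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
        noise_cv=0.0,
        replicates=1,
    )
    states = simulate_labeling(config)
    for state in states:
        expected = purity * (1.0 - np.exp(-state.time_min / tau))
        assert mean_enrichment(state.distributions["X"]) == pytest.approx(expected, abs=1e-6)


def test_distributions_normalized_at_all_times(wt_noiseless_states):
    _, states = wt_noiseless_states
    for state in states:
        for dist in state.distributions.values():
            assert abs(dist.fractions.sum() - 1.0) <= 1e-9
            assert np.all(dist.fractions >= 0)


def test_measurement_layer_roundtrip_zero_noise(wt_noiseless_states):
    config, states = wt_noiseless_states
    raw = apply_measurement_layer(states, config)
    true_by_time = {s.time_min: s.distributions for s in states}
    for (time_min, metabolite), group in raw.groupby(["time_min", "metabolite"]):
        group = group.sort_values("m_index")
        model = build_correction_model(
            len(group) - 1, config.natural_13c_abundance, config.tracer_purity
        )
        recovered = correct_spectrum(group["intensity"].to_numpy(), model)
        np.testing.assert_allclose(
            recovered.distribution.fractions,
            true_by_time[time_min][metabolite].fractions,
            atol=1e-8,
        )


def test_measurement_layer_deterministic_per_seed(wt_noiseless_states, pathway):
    _, states = wt_noiseless_states
    cfg = lambda seed: strain_config(
        "WT", pathway=pathway, noise_cv=0.1, replicates=2, rng_seed=seed
    )
    a = apply_measurement_layer(states, cfg(7))
    b = apply_measurement_layer(states, cfg(7))
    c = apply_measurement_layer(states, cfg(8))
    assert a.equals(b)
    assert not np.allclose(a["intensity"], c["intensity"])


def test_label_arrival_follows_pathway_order(wt_enrichment_curves):
    """Half-exchange times are non-decreasing from M5P to GGPP."""
    from prenylflux.kinetics import EnrichmentSeries, fit_logistic

    times, curves = wt_enrichment_curves
    order = ["M5P", "IPP+DMAPP", "GPP", "FPP", "GGPP"]
    t50s = [
        fit_logistic(EnrichmentSeries(name, "WT", times, curves[name])).t50_min
        for name in order
    ]
    assert all(b >= a for a, b in zip(t50s, t50s[1:]))
    assert t50s[0] > 0


def test_flux_pool_scaling_invariance(pathway, wt_noiseless_states):
    """Scaling all pools AND the flux by lambda leaves labeling unchanged."""
    _, base_states = wt_noiseless_states
    scaled_cfg = strain_config("S037", pathway=pathway, noise_cv=0.0, replicates=1)
    scaled_states = simulate_labeling(scaled_cfg)
    for a, b in zip(base_states, scaled_states):
        for name in a.distributions:
            np.testing.assert_allclose(
                a.distributions[name].fractions, b.distributions[name].fractions, atol=1e-7
            )


def test_larger_pools_at_fixed_flux_slow_labeling(pathway, wt_enrichment_curves):
    from prenylflux.kinetics import EnrichmentSeries, fit_logistic

    times, base_curves = wt_enrichment_curves
    base = strain_config("WT", pathway=pathway, noise_cv=0.0, replicates=1)
    slow_cfg = SimulationConfig(
        pathway=pathway,
        pool_sizes={k: 3 * v for k, v in base.pool_sizes.items()},
        pathway_flux=base.pathway_flux,
        noise_cv=0.0,
        replicates=1,
    )
    slow_states = simulate_labeling(slow_cfg)
    for name in ("M5P", "GGPP"):
        slow_curve = np.array(
            [mean_enrichment(s.distributions[name]) for s in slow_states]
        )
        t50_base = fit_logistic(EnrichmentSeries(name, "a", times, base_curves[name])).t50_min
        t50_slow = fit_logistic(EnrichmentSeries(name, "b", times, slow_curve)).t50_min
        assert t50_slow > t50_base


def test_invalid_configs_rejected(pathway):
    base = strain_config("WT", pathway=pathway)
    with pytest.raises(ValueError, match="positive"):
        SimulationConfig(pathway=pathway, pool_sizes={**base.pool_sizes, "GPP": 0.0},
                         pathway_flux=0.6)
    with pytest.raises(ValueError, match="flux"):
        SimulationConfig(pathway=pathway, pool_sizes=base.pool_sizes, pathway_flux=-1.0)
    with pytest.raises(ValueError, match="timepoints"):
        SimulationConfig(pathway=pathway, pool_sizes=base.pool_sizes, pathway_flux=0.6,
                         timepoints=(1.0, 2.0))
    with pytest.raises(ValueError, match="purity"):
        SimulationConfig(pathway=pathway, pool_sizes=base.pool_sizes, pathway_flux=0.6,
                         tracer_purity=1.5)


def test_calibration_series_noise_free_is_exact_line():
    table = make_calibration_series(
        "GGPP", levels=[0.5, 1, 2, 5, 10, 20, 50], noise_cv=0.0, blank_sd_area=0.0
    )
    slope = np.polyfit(table["level_pmol"], table["ratio"], 1)[0]
    assert slope == pytest.approx(0.2, abs=1e-12)  # 1000 area/pmol over 5000 ISTD area


def test_calibration_series_saturates_above_50_pmol():
    table = make_calibration_series(
        "GGPP", levels=[10, 50, 100], noise_cv=0.0, blank_sd_area=0.0
    )
    by_level = table.groupby("level_pmol")["ratio"].mean()
    assert by_level[50] == pytest.approx(5 * by_level[10], rel=1e-9)  # linear below knee
    assert by_level[100] < 2 * by_level[50]  # compressed above it


def test_calibration_series_level_validation():
    with pytest.raises(ValueError, match="at least 2"):
        make_calibration_series("GGPP", levels=[1.0])
    with pytest.raises(ValueError, match="distinct"):
        make_calibration_series("GGPP", levels=[1.0, 1.0, 2.0])
    with pytest.warns(UserWarning, match="fewer than 5"):
        from prenylflux.idms import fit_calibration

        fit_calibration(make_calibration_series("GGPP", levels=[1, 2, 5], noise_cv=0.0))
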