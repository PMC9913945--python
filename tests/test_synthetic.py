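"""Synthetic cohort generator: sampling law, determinism, group structure."""

import numpy as np
import pytest

from erpdx.behavior import GO_TRIAL, summarize_behavior
from erpdx.erp_data import default_registry, slice_interval
from erpdx.synthetic import (
    BehaviorModel,
    CohortConfig,
    ComponentModel,
    default_components,
    simulate_cohort,
    simulate_subject,
    simulate_trials,
)
from erpdx.errors import ConfigError, ValidationError


def test_default_components_latencies_and_polarity(components):
    by_cond = {c.condition: c for c in components}
    assert by_cond["plus1"].latency_ms == 420  # midpoint of 320-520
    assert by_cond["ph"].latency_ms == 190     # midpoint of 160-220
    assert by_cond["plus2"].polarity == -1     # CNV is a negative expectancy wave
    for c in components:
        assert c.amp_patient_uv <= c.amp_healthy_uv


def test_component_model_validates():
    with pytest.raises(ConfigError):
        ComponentModel("go", 350, 50, {"Cz": 1.0}, amp_healthy_uv=5.0,
                       amp_patient_uv=6.0)  # patient > healthy
    with pytest.raises(ConfigError):
        ComponentModel("go", 350, -1, {"Cz": 1.0}, 5.0, 4.0)


def test_noise_free_subject_peak_amplitude_exact(components, registry):
    """With no noise and no subject variability, the peak equals
    amp * topography weight exactly (up to 1e-6 quantization)."""
    cfg = CohortConfig(noise_sd_uv=0.0, seed=0)
    comps = [ComponentModel(c.condition, c.latency_ms, c.width_ms, c.topography,
                            c.amp_healthy_uv, c.amp_patient_uv, c.polarity,
                            subject_sd_frac=0.0) for c in components]
    rec = simulate_subject("healthy", comps, cfg, np.random.default_rng(0),
                           registry=registry)
    for c in comps:
        spec = registry[c.condition]
        for ch in spec.channels:
            w = rec.erps[(c.condition, ch)]
            t = w.times_ms()
            k = int(np.argmin(np.abs(t - c.latency_ms)))
            # evaluate the bump at the nearest grid sample (the latency
            # midpoint of plus2, 990 ms, is off the 4 ms grid)
            bump = np.exp(-((t[k] - c.latency_ms) ** 2) / (2 * c.width_ms ** 2))
            expected = c.polarity * c.amp_healthy_uv * c.topography[ch] * bump
            assert w.samples[k] == pytest.approx(expected, abs=1e-5)
            if t[k] == c.latency_ms:  # on-grid latencies peak exactly
                assert abs(w.samples[k]) == pytest.approx(
                    c.amp_healthy_uv * c.topography[ch], abs=1e-5)


def test_waveform_covers_interval_with_margin(small_cohort):
    reg = small_cohort.registry
    for spec in reg:
        w = small_cohort.subjects[0].erps[(spec.name, spec.channels[0])]
        assert slice_interval(w, spec).size == spec.n_interval_samples(250.0)
        # 100 ms margin = 25 samples on each side at 250 Hz
        assert w.samples.size == spec.n_interval_samples(250.0) + 50


def test_cohort_counts_and_ids():
    ds = simulate_cohort(CohortConfig(n_healthy=5, n_patient=3, seed=1))
    assert len(ds) == 8
    assert ds.n_by_group() == {"healthy": 5, "schizophrenia": 3}
    assert ds.subjects[0].subject_id == "h001"
    assert ds.subjects[5].subject_id == "p001"


def test_cohort_determinism_and_seed_sensitivity():
    cfg = CohortConfig(n_healthy=4, n_patient=3, seed=11)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    key = ("plus1", "O1")
    for sa, sb in zip(a.subjects, b.subjects):
        np.testing.assert_array_equal(sa.erps[key].samples, sb.erps[key].samples)
        assert sa.behavior.as_tuple() == sb.behavior.as_tuple()
    c = simulate_cohort(CohortConfig(n_healthy=4, n_patient=3, seed=12))
    assert not np.array_equal(a.subjects[0].erps[key].samples,
                              c.subjects[0].erps[key].samples)


def test_subject_streams_stable_under_count_change():
    """Growing the cohort leaves earlier subjects of the same group unchanged."""
    a = simulate_cohort(CohortConfig(n_healthy=4, n_patient=2, seed=5))
    b = simulate_cohort(CohortConfig(n_healthy=6, n_patient=2, seed=5))
    key = ("go", "Cz")
    for i in range(4):
        np.testing.assert_array_equal(a.subjects[i].erps[key].samples,
                                      b.subjects[i].erps[key].samples)


def test_null_cohort_group_distributions_identical(components):
    """At effect_scale 0 patient draws follow the healthy law exactly:
    the same substream yields the same subject under either label."""
    cfg = CohortConfig(effect_scale=0.0, seed=2)
    rec_h = simulate_subject("healthy", components, cfg,
                             np.random.default_rng([2, 0]))
    rec_p = simulate_subject("schizophrenia", components, cfg,
                             np.random.default_rng([2, 0]))
    for key in rec_h.erps:
        np.testing.assert_array_equal(rec_h.erps[key].samples,
                                      rec_p.erps[key].samples)
    assert rec_h.behavior.as_tuple() == rec_p.behavior.as_tuple()


def test_patient_amplitude_sampling_law(components):
    """Monte-Carlo check: mean peak amplitude over many patient draws is
    within 3 standard errors of the patient group mean."""
    comp = [c for c in components if c.condition == "go"][0]
    cfg = CohortConfig(noise_sd_uv=0.0, seed=0)
    reg = default_registry()
    n = 1000
    rng = np.random.default_rng(123)
    peaks = []
    for _ in range(n):
        rec = simulate_subject("schizophrenia", [comp], cfg, rng, registry=reg)
        w = rec.erps[("go", "Cz")]
        peaks.append(w.samples.max())  # Cz weight is 1.0
    mean = np.mean(peaks)
    # truncation at 0 is negligible at amp/sd = 4
    se = comp.subject_sd_frac * comp.amp_patient_uv / np.sqrt(n)
    assert abs(mean - comp.amp_patient_uv) < 3 * se


def test_group_grand_average_difference_sign(medium_cohort, components):
    """Healthy minus patient grand average at the component latency has the
    component's polarity sign on every weighted channel."""
    reg = medium_cohort.registry
    for comp in components:
        spec = reg[comp.condition]
        for ch in spec.channels:
            if comp.topography.get(ch, 0) <= 0:
                continue
            h, p = [], []
            for s in medium_cohort.subjects:
                w = s.erps[(comp.condition, ch)]
                k = int(np.argmin(np.abs(w.times_ms() - comp.latency_ms)))
                (h if s.group == "healthy" else p).append(w.samples[k])
            diff = np.mean(h) - np.mean(p)
            assert np.sign(diff) == comp.polarity, (comp.condition, ch)


def test_invalid_group_label_rejected(components):
    with pytest.raises(ValidationError):
        simulate_subject("martian", components, CohortConfig(),
                         np.random.default_rng(0))


def test_behavior_draw_means_recovered():
    """Draws reproduce configured means within 3 SE when clipping is inactive."""
    model = BehaviorModel({
        "healthy": {"miss_pct": (50.0, 5.0), "false_click_pct": (40.0, 5.0),
                    "rt_ms": (500.0, 50.0), "rt_var": (20.0, 3.0)},
        "schizophrenia": {"miss_pct": (50.0, 5.0), "false_click_pct": (40.0, 5.0),
                          "rt_ms": (500.0, 50.0), "rt_var": (20.0, 3.0)},
    })
    rng = np.random.default_rng(0)
    n = 10_000
    draws = np.array([model.draw("healthy", rng).as_tuple() for _ in range(n)])
    for j, (mu, sd) in enumerate([(50, 5), (40, 5), (500, 50), (20, 3)]):
        assert abs(draws[:, j].mean() - mu) < 3 * sd / np.sqrt(n)


def test_behavior_clipping():
    model = BehaviorModel({
        "healthy": {"miss_pct": (0.5, 10.0), "false_click_pct": (0.5, 10.0),
                    "rt_ms": (250.0, 200.0), "rt_var": (5.0, 10.0)},
        "schizophrenia": {"miss_pct": (0.5, 10.0), "false_click_pct": (0.5, 10.0),
                          "rt_ms": (250.0, 200.0), "rt_var": (5.0, 10.0)},
    })
    rng = np.random.default_rng(1)
    for _ in range(200):
        b = model.draw("healthy", rng)
        assert 0 <= b.miss_pct <= 100
        assert 0 <= b.false_click_pct <= 100
        assert 200 <= b.rt_ms <= 1000


def _fresh_subject():
    return simulate_cohort(CohortConfig(n_healthy=2, n_patient=2, seed=77)).subjects[0]


def test_simulate_trials_edge_rates(rng):
    subj = _fresh_subject()
    subj.behavior.miss_pct = 0.0
    trials = simulate_trials(subj, 100, 50, rng)
    go = [t for t in trials if t.trial_type == GO_TRIAL]
    assert len(go) == 100 and all(t.pressed for t in go)

    subj.behavior.miss_pct = 100.0
    trials = simulate_trials(subj, 50, 50, rng)
    assert not any(t.pressed for t in trials if t.trial_type == GO_TRIAL)


def test_simulate_trials_binomial_miss_rate(rng):
    subj = _fresh_subject()
    subj.behavior.miss_pct = 10.0
    n = 10_000
    trials = simulate_trials(subj, n, 10, rng)
    missed = sum(not t.pressed for t in trials if t.trial_type == GO_TRIAL)
    se = np.sqrt(0.1 * 0.9 / n)
    assert abs(missed / n - 0.10) < 3 * se


def test_trials_round_trip_through_summary():
    """summarize_behavior over simulated trials recovers the generating
    miss rate within binomial error."""
    subj = _fresh_subject()
    subj.behavior.miss_pct = 20.0
    trials = simulate_trials(subj, 5000, 5000, np.random.default_rng(9))
    summ = summarize_behavior(trials)
    assert abs(summ.miss_pct - 20.0) < 3 * 100 * np.sqrt(0.2 * 0.8 / 5000)
    assert abs(summ.rt_ms - subj.behavior.rt_ms) < 10


def test_cohort_config_validation():
    with pytest.raises(ConfigError):
        CohortConfig(n_healthy=1)
    with pytest.raises(ConfigError):
        CohortConfig(effect_scale=1.5)
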