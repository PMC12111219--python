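import dataclasses

import numpy as np
import pytest

from hydrolens.optics import refractive_index_from_angles
from hydrolens.stats import wilcoxon_signed_rank_exact
from hydrolens.swelling import auc, expansion_series, factor_at, water_content
from hydrolens.synthetic import (
    SwellKineticsParams,
    contaflex_preset,
    gen_cohort,
    gen_lidar_trace,
    gen_masses,
    gen_refraction_obs,
    gen_swelling_series,
    solve_kinetics_from_anchors,
    swelling_factor_curve,
)


def test_noiseless_kinetics_start_at_one_and_hit_both_anchors():
    p = solve_kinetics_from_anchors(1.499, 1.563, tau=2.5, noise_sd=0.0,
                                    dry_reference=10.0)
    f = swelling_factor_curve(p, np.array([0.0, 17.0, 24.0]))
    assert f[0] == pytest.approx(1.0, abs=1e-12)
    assert f[1] == pytest.approx(1.499, abs=1e-12)
    assert f[2] == pytest.approx(1.563, abs=1e-12)


def test_reversed_anchors_rejected():
    with pytest.raises(ValueError):
        solve_kinetics_from_anchors(1.563, 1.499, tau=2.5, noise_sd=0.0,
                                    dry_reference=10.0)


def test_swelling_series_seed_determinism():
    p = SwellKineticsParams(plateau=1.5, tau=2.5, creep=0.002, noise_sd=0.01,
                            dry_reference=10.0)
    a = gen_swelling_series(p, "lateral", rng=42)
    b = gen_swelling_series(p, "lateral", rng=42)
    assert np.array_equal(a.values, b.values)
    c = gen_swelling_series(p, "lateral", rng=43)
    assert not np.array_equal(a.values, c.values)


def test_preset_noiseless_anchors_match_published_means(registry):
    cfg = contaflex_preset(noiseless=True)
    for (name, direction), p in cfg.kinetics.items():
        spec = registry[name]
        a17, a24 = (
            (spec.lef_17h.mean, spec.lef_24h.mean)
            if direction == "lateral"
            else (spec.ref_17h.mean, spec.ref_24h.mean)
        )
        f = swelling_factor_curve(p, np.array([17.0, 24.0]))
        assert f[0] == pytest.approx(a17, abs=1e-12)
        assert f[1] == pytest.approx(a24, abs=1e-12)
        assert p.noise_sd == 0.0


def test_mass_generator_round_trip_and_clipping():
    pair, clipped = gen_masses(50.0, m_dry=1.0)
    assert pair.m_swollen == pytest.approx(2.0) and not clipped
    pair, _ = gen_masses(63.7, m_dry=0.363)
    assert water_content(pair) == pytest.approx(63.7, abs=1e-12)
    # enormous noise must eventually clip, never produce m1 < m0
    clip_seen = False
    for seed in range(30):
        pair, clipped = gen_masses(10.0, m_dry=1.0, noise_sd=1.0, rng=seed)
        assert pair.m_swollen >= pair.m_dry
        clip_seen = clip_seen or clipped
    assert clip_seen
    with pytest.raises(ValueError):
        gen_masses(120.0)


def test_refraction_generator_round_trip_and_determinism():
    obs = gen_refraction_obs(1.552, theta_air=60.0)
    assert refractive_index_from_angles(obs) == pytest.approx(1.552, abs=1e-12)
    obs1 = gen_refraction_obs(1.4, angle_noise_deg=0.5, rng=5)
    obs2 = gen_refraction_obs(1.4, angle_noise_deg=0.5, rng=5)
    assert obs1 == obs2
    assert gen_refraction_obs(1.0).theta_gel == pytest.approx(60.0)


def test_lidar_generator_truth_and_ordering_checks():
    trace, truth = gen_lidar_trace(noise_sd=0.0)
    i_min = int(np.argmin(trace.distances))
    assert trace.times[i_min] / 3600.0 == pytest.approx(truth.growth_end, abs=0.01)
    i_max = int(np.argmax(trace.distances))
    assert trace.times[i_max] / 3600.0 == pytest.approx(
        truth.transparency_peak, abs=0.01
    )
    with pytest.raises(ValueError):
        gen_lidar_trace(dip_time=9.0, peak_time=2.0)


def test_cohort_counts_and_determinism():
    cfg = dataclasses.replace(
        contaflex_preset(seed=11),
        times=np.arange(0.0, 24.0 + 1e-9, 1.0),
        lidar_duration_h=13.0,
        lidar_fs_hz=0.05,
    )
    cohort = gen_cohort(cfg)
    assert len(cohort.samples) == 25
    assert len(cohort.truth["kinetics"]) == 10  # 5 groups x 2 directions
    again = gen_cohort(cfg)
    for a, b in zip(cohort.samples, again.samples):
        assert np.array_equal(a.lateral.values, b.lateral.values)
        assert a.mass == b.mass and a.refraction == b.refraction
    with pytest.raises(ValueError):
        dataclasses.replace(cfg, samples_per_group=0)


def test_noisy_cohort_recovers_preset_plateaus(noisy_cohort):
    """Group means at 24 h within 2*noise_sd/sqrt(n) of the preset anchor."""
    cfg = noisy_cohort.config
    by_group = {}
    for s in noisy_cohort.samples:
        by_group.setdefault(s.group, []).append(s)
    for (name, direction), p in cfg.kinetics.items():
        anchor = swelling_factor_curve(p, np.array([24.0]))[0]
        attr = "lateral" if direction == "lateral" else "sagittal"
        vals = [
            factor_at(expansion_series(getattr(s, attr)), 24.0)
            for s in by_group[name]
        ]
        n = len(vals)
        assert np.mean(vals) == pytest.approx(
            anchor, abs=max(2 * p.noise_sd / np.sqrt(n), 1e-12)
        )


def test_noiseless_chain_is_exact_to_1e12(noiseless_cohort):
    s = next(x for x in noiseless_cohort.samples if x.group == "C77")
    es = expansion_series(s.lateral)
    assert factor_at(es, 24.0) == pytest.approx(1.563, abs=1e-12)
    assert factor_at(es, 17.0) == pytest.approx(1.499, abs=1e-12)


def test_positive_growth_links_generator_to_exact_wilcoxon(noisy_cohort):
    """Cumulative AUC grows in every sample, so each group's paired test
    at n=5 lands exactly on the two-sided enumeration floor 2/2^5."""
    by_group = {}
    for s in noisy_cohort.samples:
        by_group.setdefault(s.group, []).append(s)
    for name, members in by_group.items():
        diffs = []
        for s in members:
            es = expansion_series(s.lateral)
            diffs.append(auc(es, 0.0, 24.0) - auc(es, 0.0, 17.0))
        assert all(d > 0 for d in diffs)
        assert wilcoxon_signed_rank_exact(diffs).p_two_sided == pytest.approx(0.0625)
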