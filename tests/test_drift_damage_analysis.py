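"""Sequential-bin drift statistics, Wilson B fits and damage ratios."""

import numpy as np
import pytest

from ssrox import (
    DOSE_CONDITIONS,
    DamageModel,
    DriftModel,
    HitModel,
    NoiseModel,
    ScanGeometry,
    b_ratio_series,
    bin_cell_drift,
    default_config,
    dose_per_image,
    estimate_image_scales,
    monte_carlo_merge,
    percent_change,
    simulate_stream,
    wilson_b,
)


def _stream(truth, drift, n_images=400, seed=2, hits=None, noise=None):
    cfg = default_config()
    return simulate_stream(
        truth, ScanGeometry(1, n_images), cfg.beam,
        hits or HitModel(lambda_crystals=5.0, q1=1.0, gamma_multi=1.0),
        drift, DamageModel(beta=0.0),
        noise or NoiseModel(obs_fraction=0.05), seed=seed,
    )


def test_constant_cell_gives_identical_bins(coarse_truth):
    stream = _stream(coarse_truth, DriftModel.constant(coarse_truth.cell), 200)
    bins = bin_cell_drift(stream, 10)
    assert np.allclose(bins["mean_a"], coarse_truth.cell.a)
    assert np.allclose(bins["std_c"], 0.0)
    assert bins["n_indexed"].sum() == sum(im.indexed for im in stream.images)


def test_linear_drift_bins_match_trajectory_means(coarse_truth):
    """With every image indexed and no jitter, bin means are exact averages
    of the linear trajectory over the bin's image indices."""
    drift = DriftModel.tetragonal_drift(78.44, 78.34, 38.38, 38.79, knot=1.0)
    n = 400
    stream = _stream(coarse_truth, drift, n)
    bins = bin_cell_drift(stream, 10)
    frac = np.arange(n) / (n - 1)
    traj_c = 38.38 + (38.79 - 38.38) * frac
    indexed = np.array([im.indexed for im in stream.images])
    for _, row in bins.iterrows():
        members = np.arange(int(row.i_low), int(row.i_high))
        members = members[indexed[members]]
        assert row.mean_c == pytest.approx(traj_c[members].mean(), abs=1e-9)


def test_plateau_drift_reproduces_early_and_late_bin_levels(coarse_truth):
    drift = DriftModel.tetragonal_drift(78.44, 78.34, 38.38, 38.79, knot=0.5)
    stream = _stream(coarse_truth, drift, 500)
    bins = bin_cell_drift(stream, 10)
    assert bins["mean_c"].iloc[0] == pytest.approx(38.42, abs=0.02)
    assert bins["mean_c"].iloc[-1] == pytest.approx(38.79, abs=0.005)
    # late bins sit on the plateau
    assert np.allclose(bins["mean_c"].iloc[6:], 38.79, atol=0.005)


def test_bins_partition_image_range(coarse_truth):
    stream = _stream(coarse_truth, DriftModel.constant(coarse_truth.cell), 103)
    bins = bin_cell_drift(stream, 10)
    assert bins["i_low"].iloc[0] == 0
    assert bins["i_high"].iloc[-1] == 103
    assert (bins["i_low"].iloc[1:].to_numpy() == bins["i_high"].iloc[:-1].to_numpy()).all()


def test_percent_change_examples():
    assert percent_change(38.38, 38.79) == pytest.approx(1.068, abs=1e-3)
    assert round(percent_change(38.38, 38.79)) == 1
    assert percent_change(5.0, 5.0) == 0.0
    assert percent_change(78.44, 78.34) == pytest.approx(-0.127, abs=1e-3)
    with pytest.raises(ValueError):
        percent_change(0.0, 1.0)


def test_wilson_b_recovers_generative_b(coarse_truth):
    """Low-noise merge of an undamaged stream returns B ≈ B_true."""
    noise = NoiseModel(obs_fraction=0.15, scale_sigma=0.1, gain=2.1e-8,
                       read_noise=0.0, background_per_photon=0.0)
    stream = _stream(coarse_truth, DriftModel.constant(coarse_truth.cell),
                     400, noise=noise)
    merged = monte_carlo_merge(stream, estimate_image_scales(stream))
    fit = wilson_b(merged, s_min=0.02)
    assert fit.b_wilson == pytest.approx(13.0, rel=0.05)


def test_wilson_b_shifts_by_applied_damage(coarse_truth):
    """Dose D with growth beta and fraction f gives B ≈ B_true + beta·f·D."""
    cfg = default_config()
    beam = DOSE_CONDITIONS[830.0]
    damage = DamageModel(beta=15.0, dose_fraction_applied=0.5)
    noise = NoiseModel(obs_fraction=0.1, scale_sigma=0.1, gain=2.1e-8,
                       read_noise=0.0, background_per_photon=0.0)
    stream = simulate_stream(
        coarse_truth, ScanGeometry(1, 400), beam,
        HitModel(lambda_crystals=5.0, q1=1.0, gamma_multi=1.0),
        DriftModel.constant(coarse_truth.cell), damage, noise, seed=6,
    )
    merged = monte_carlo_merge(stream, estimate_image_scales(stream))
    fit = wilson_b(merged, s_min=0.02)
    expected = 13.0 + 15.0 * 0.5 * dose_per_image(beam) / 1000.0
    assert fit.b_wilson == pytest.approx(expected, rel=0.10)


def test_b_ratio_series_reference_values():
    assert b_ratio_series(13.16, [13.16, 13.16]) == [1.0, 1.0]
    assert b_ratio_series(13.16, [23.18])[0] == pytest.approx(0.568, abs=1e-3)
    ratios = b_ratio_series(13.16, [13.13, 13.60, 15.46, 19.02, 23.18])
    assert all(a > b for a, b in zip(ratios[1:], ratios[2:]))  # decreasing in B_n
    with pytest.raises(ValueError):
        b_ratio_series(13.16, [0.0])
    with pytest.raises(ValueError):
        b_ratio_series(-1.0, [13.0])
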