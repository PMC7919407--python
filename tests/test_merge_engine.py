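"""Lorentz correction, per-image scaling, Monte Carlo merging, half-set stats."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssrox import (
    HitModel,
    NoiseModel,
    ScanGeometry,
    UnitCell,
    cc_half,
    default_config,
    estimate_image_scales,
    lorentz_factor,
    monte_carlo_merge,
    rsplit,
    shell_statistics,
    simulate_stream,
)
from ssrox.dose import BeamCondition
from ssrox.simulate import (
    DamageModel,
    DriftModel,
    ImageRecord,
    Observations,
    ObservationStream,
    StreamMeta,
)


def test_lorentz_hand_trigonometry():
    # wavelength 1 Å, d = 2 Å: sinθ = 0.25, 2θ = 28.955°, L = 1/sin(2θ)
    assert lorentz_factor(0.25, 1.0) == pytest.approx(2.0656, abs=1e-4)


def test_lorentz_monotone_decreasing_while_two_theta_below_90():
    s = np.linspace(1 / 10.0**2, 1 / 1.4**2, 200)
    L = lorentz_factor(s, 1.0)
    assert np.all(np.diff(L) < 0)


def test_lorentz_rejects_reflections_outside_sphere():
    with pytest.raises(ValueError):
        lorentz_factor(4.1, 1.0)  # sinθ > 1
    with pytest.raises(ValueError):
        lorentz_factor(0.0, 1.0)


def _toy_stream(image_intensities, cell=None, hkl=None):
    """Stream with given per-image intensity lists over a common hkl set."""
    cell = cell or UnitCell.tetragonal(20.0, 10.0)
    n_refl = len(image_intensities[0])
    if hkl is None:
        hkl = np.array([[1 + j, 0, 0] for j in range(n_refl)], np.int32)
    beam = BeamCondition(1e12, 1.0, 100.0, 1.0, wavelength=1.0)
    meta = StreamMeta(
        cell=cell,
        laue="identity",
        d_min=2.0,
        geometry=ScanGeometry(1, len(image_intensities)),
        beam=beam,
        seed=0,
    )
    images = []
    for i, intens in enumerate(image_intensities):
        obs = Observations(hkl, np.asarray(intens, float), np.ones(n_refl))
        images.append(
            ImageRecord(i, 0, 0.0, cell, 1, True, True, obs)
        )
    return ObservationStream(images, meta)


def test_identical_images_all_get_unit_scale():
    base = [10.0, 20.0, 30.0, 40.0]
    stream = _toy_stream([base] * 4)
    result = estimate_image_scales(stream, n_iterations=2)
    assert np.allclose(result.scales.to_numpy(), 1.0, atol=1e-12)
    assert result.n_flagged == 0


def test_doubled_image_gets_double_scale():
    base = [10.0, 20.0, 30.0, 40.0]
    stream = _toy_stream([base, base, base, [2 * v for v in base]])
    scales = estimate_image_scales(stream, n_iterations=2).scales
    assert scales[3] / scales[0] == pytest.approx(2.0, abs=1e-6)


def test_scale_recovery_correlates_with_hidden_truth():
    """Log-normal simulator scales are recovered from low-noise data.

    Every image observes the full truth set with negligible counting noise;
    the residual scatter is the per-observation partiality draw.
    """
    from ssrox import generate_truth

    truth = generate_truth(
        UnitCell.tetragonal(78.4, 38.4), 2.0, 13.0, 100.0, "4/mmm", seed=101
    )
    cfg = default_config()
    noise = NoiseModel(
        obs_fraction=1.0, scale_sigma=1.0, gain=2.1e-7, read_noise=0.0,
        background_per_photon=0.0,
    )
    stream = simulate_stream(
        truth, ScanGeometry(1, 100), cfg.beam, HitModel(q1=1.0),
        DriftModel.constant(truth.cell), DamageModel(beta=0.0), noise, seed=21,
    )
    est = estimate_image_scales(stream, n_iterations=5).scales
    true = np.array([stream.images[i].true_scale for i in est.index])
    r = np.corrcoef(true, est.to_numpy())[0, 1]
    assert r >= 0.999


def test_merge_single_observation_flags_sigma():
    stream = _toy_stream([[5.0]])
    merged = monte_carlo_merge(stream)
    row = merged.table.iloc[0]
    assert row["m"] == 1 and math.isnan(row["sigma"])
    # intensity equals the Lorentz-corrected observation
    s = stream.meta.cell.s_of_hkl(np.array([[1, 0, 0]]))[0]
    assert row["i_merged"] == pytest.approx(5.0 / lorentz_factor(s, 1.0), rel=1e-12)


def test_parity_split_on_ten_images():
    stream = _toy_stream([[7.0]] * 10)
    merged = monte_carlo_merge(stream)
    row = merged.table.iloc[0]
    assert (row["n_even"], row["n_odd"]) == (5, 5)
    assert row["m"] == 10


def test_noiseless_merge_recovers_scaled_lorentz_corrected_truth(coarse_truth):
    """Observations built as I_true·L·g merge back to I_true exactly."""
    n = 60
    rng = np.random.default_rng(0)
    g = np.exp(rng.normal(0, 0.3, n))
    s = coarse_truth.s
    L = lorentz_factor(s, 1.0)
    meta = StreamMeta(
        cell=coarse_truth.cell, laue="4/mmm", d_min=coarse_truth.d_min,
        geometry=ScanGeometry(1, n),
        beam=BeamCondition(1e12, 1.0, 100.0, 1.0, wavelength=1.0), seed=0,
    )
    images = [
        ImageRecord(
            i, 0, 0.0, coarse_truth.cell, 1, True, True,
            Observations(coarse_truth.hkl, coarse_truth.i_true * L * g[i], np.ones(len(s))),
        )
        for i in range(n)
    ]
    stream = ObservationStream(images, meta)
    merged = monte_carlo_merge(stream, pd.Series(g, index=np.arange(n)))
    table = merged.table.set_index(["h", "k", "l"])
    truth_df = coarse_truth.as_frame().set_index(["h", "k", "l"])
    joined = table.join(truth_df[["i_true"]])
    assert np.allclose(joined["i_merged"], joined["i_true"], rtol=1e-9)


def test_rsplit_identical_halves_is_zero_and_hand_value():
    df = pd.DataFrame(
        {"i_even": [10.0, 20.0], "i_odd": [10.0, 20.0], "n_even": 1, "n_odd": 1}
    )
    assert rsplit(df) == 0.0
    df2 = pd.DataFrame(
        {"i_even": [10.0, 20.0], "i_odd": [12.0, 18.0], "n_even": 1, "n_odd": 1}
    )
    assert rsplit(df2) == pytest.approx(100.0 / math.sqrt(2) * 4 / 30, rel=1e-12)
    assert rsplit(df2) == pytest.approx(9.428, abs=1e-3)


@given(factor=st.floats(1e-3, 1e3))
def test_rsplit_scale_invariance(factor):
    df = pd.DataFrame(
        {"i_even": [10.0, 20.0, 5.0], "i_odd": [12.0, 18.0, 6.0], "n_even": 1, "n_odd": 1}
    )
    scaled = df.assign(i_even=df.i_even * factor, i_odd=df.i_odd * factor)
    assert rsplit(scaled) == pytest.approx(rsplit(df), rel=1e-9)


def test_cc_half_limits_and_flags():
    sig = np.array([1.0, 5.0, 2.0, 8.0, 3.0])
    df = pd.DataFrame({"i_even": sig, "i_odd": sig, "n_even": 1, "n_odd": 1})
    assert cc_half(df) == pytest.approx(1.0)
    assert cc_half(df.assign(i_odd=-sig)) == pytest.approx(-1.0)
    assert math.isnan(cc_half(df.iloc[:2]))  # fewer than 3 pairs
    flat = pd.DataFrame({"i_even": [1.0] * 5, "i_odd": sig, "n_even": 1, "n_odd": 1})
    assert math.isnan(cc_half(flat))  # zero variance


def test_cc_half_matches_noise_variance_expectation():
    """CC ≈ σ_I²/(σ_I² + σ_ε²) for independent half noise (3 SE tolerance)."""
    rng = np.random.default_rng(12)
    n = 2000
    sig_i, sig_e = 2.0, 1.0
    signal = rng.normal(0, sig_i, n)
    df = pd.DataFrame(
        {
            "i_even": signal + rng.normal(0, sig_e, n),
            "i_odd": signal + rng.normal(0, sig_e, n),
            "n_even": 1,
            "n_odd": 1,
        }
    )
    expected = sig_i**2 / (sig_i**2 + sig_e**2)
    se = (1 - expected**2) / math.sqrt(n)
    assert cc_half(df) == pytest.approx(expected, abs=3 * se)


def test_rmse_halves_when_images_quadruple(coarse_truth):
    """Monte Carlo convergence: merged-vs-truth RMSE scales as m^{-1/2}."""
    rng = np.random.default_rng(5)
    s = coarse_truth.s
    L = lorentz_factor(s, 1.0)

    def rmse(n_images):
        images = []
        meta = StreamMeta(
            cell=coarse_truth.cell, laue="4/mmm", d_min=coarse_truth.d_min,
            geometry=ScanGeometry(1, n_images),
            beam=BeamCondition(1e12, 1.0, 100.0, 1.0, wavelength=1.0), seed=0,
        )
        for i in range(n_images):
            noisy = coarse_truth.i_true + rng.normal(0, 20.0, len(s))
            images.append(
                ImageRecord(i, 0, 0.0, coarse_truth.cell, 1, True, True,
                            Observations(coarse_truth.hkl, noisy * L, np.ones(len(s))))
            )
        merged = monte_carlo_merge(ObservationStream(images, meta))
        joined = (
            merged.table.set_index(["h", "k", "l"])
            .join(coarse_truth.as_frame().set_index(["h", "k", "l"])[["i_true"]])
        )
        return float(np.sqrt(((joined["i_merged"] - joined["i_true"]) ** 2).mean()))

    ratio = rmse(30) / rmse(120)
    assert ratio == pytest.approx(2.0, rel=0.2)


def test_half_set_residuals_are_uncorrelated(mini_stream, coarse_truth):
    merged = monte_carlo_merge(mini_stream, estimate_image_scales(mini_stream))
    table = merged.table[(merged.table.n_even > 1) & (merged.table.n_odd > 1)]
    joined = (
        table.set_index(["h", "k", "l"])
        .join(coarse_truth.as_frame().set_index(["h", "k", "l"])[["i_true"]])
    )
    x = joined["i_true"].to_numpy()
    e = joined["i_even"].to_numpy() - np.polyval(np.polyfit(x, joined["i_even"], 1), x)
    o = joined["i_odd"].to_numpy() - np.polyval(np.polyfit(x, joined["i_odd"], 1), x)
    r = np.corrcoef(e, o)[0, 1]
    n = len(e)
    # moment-based SE valid under heteroskedastic residuals
    se = math.sqrt(np.mean(e**2 * o**2) / (n * np.mean(e**2) * np.mean(o**2)))
    assert abs(r) < 3 * se + 1e-9


def test_shells_partition_and_report_full_completeness(coarse_truth, coarse_possible, mini_stream):
    merged = monte_carlo_merge(mini_stream)
    shells = shell_statistics(merged, coarse_possible, 10)
    # partition: contiguous, no overlaps, covers (0, s_max]
    assert shells["s_low"].iloc[0] == 0.0
    assert np.allclose(shells["s_high"].iloc[:-1], shells["s_low"].iloc[1:])
    assert shells["s_high"].iloc[-1] == pytest.approx(coarse_possible["s"].max())
    assert shells["n_possible"].sum() == len(coarse_possible)
    # every possible reflection observed at 300 images and 20% sampling
    assert (shells["completeness"] == 100.0).all()
    assert shells["cc_half"].between(-1, 1).all()


def test_more_images_do_not_worsen_highest_shell_cc(coarse_truth, coarse_possible, mini_stream):
    few = ObservationStream(mini_stream.images[:30], mini_stream.meta)
    cc_many = shell_statistics(monte_carlo_merge(mini_stream), coarse_possible, 8)["cc_half"].iloc[-1]
    cc_few = shell_statistics(monte_carlo_merge(few), coarse_possible, 8)["cc_half"].iloc[-1]
    assert cc_many >= cc_few
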