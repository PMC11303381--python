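"""Synthetic scene rendering, the shot+read noise model, and the
repeat-averaging protocol."""

from __future__ import annotations

import numpy as np
import pytest

from cnnt.metrics import psnr
from cnnt.synthetic import (NoiseConfig, SceneConfig, degrade,
                            generate_clean_scene, generate_repeats,
                            make_paired_dataset, running_average)


SHAPE = (6, 48, 48)


@pytest.mark.parametrize("structure", ["filaments", "puncta", "membranes", "mixed"])
def test_scene_deterministic_and_finite(structure):
    cfg = SceneConfig(structure=structure, volume_shape=SHAPE, n_objects=6, seed=3)
    a = generate_clean_scene(cfg)
    b = generate_clean_scene(cfg)
    assert np.array_equal(a.voxels, b.voxels)
    assert a.shape == SHAPE and np.isfinite(a.voxels).all()
    assert a.voxels.min() >= cfg.background - 1e-5
    assert a.voxels.max() == pytest.approx(cfg.background + cfg.max_intensity, rel=1e-5)


def test_scene_no_objects_is_background():
    cfg = SceneConfig(volume_shape=SHAPE, n_objects=0, background=5.0)
    v = generate_clean_scene(cfg)
    assert np.allclose(v.voxels, 5.0)


def test_puncta_integrated_intensity_matches_gaussian_integral():
    """Each punctum deposits a unit impulse blurred by a unit-integral PSF,
    then the volume is scaled so the peak hits max_intensity; total signal
    must equal n_objects x (per-spot integral) up to overlap/edge effects."""
    cfg = SceneConfig(structure="puncta", volume_shape=(16, 64, 64), n_objects=8,
                      psf_sigma=(1.0, 1.5, 1.5), background=0.0,
                      max_intensity=50.0, seed=11)
    v = generate_clean_scene(cfg).voxels
    # analytic: unit impulse * unit-integral gaussian has integral 1 and peak
    # 1/((2pi)^{3/2} sz sy sx); scaling the peak to max_intensity scales each
    # spot integral to max_intensity / gauss_peak
    gauss_peak = 1.0 / ((2 * np.pi) ** 1.5 * 1.0 * 1.5 * 1.5)
    expected_total = cfg.n_objects * cfg.max_intensity / gauss_peak
    assert v.sum() == pytest.approx(expected_total, rel=0.05)


def test_degrade_deterministic_and_registered():
    clean = generate_clean_scene(SceneConfig(volume_shape=SHAPE, seed=1))
    noise = NoiseConfig(photons_high=200, exposure_ratio=0.25, seed=7)
    a = degrade(clean, noise, "low")
    b = degrade(clean, noise, "low")
    assert np.array_equal(a.voxels, b.voxels)
    assert a.shape == clean.shape


def test_degrade_large_photon_limit():
    clean = generate_clean_scene(SceneConfig(volume_shape=SHAPE, seed=2,
                                             background=20.0))
    noise = NoiseConfig(photons_high=1e6, exposure_ratio=1.0, read_sigma=0.0, seed=0)
    out = degrade(clean, noise, "high")
    rel = np.abs(out.voxels - clean.voxels) / clean.voxels
    assert rel.mean() < 0.01 and rel.max() < 0.05


def test_degrade_noise_ratio_between_arms():
    """Quarter exposure doubles the shot-noise standard deviation."""
    const = np.full((4, 64, 64), 80.0, dtype=np.float32)
    from cnnt.data_io import ImageVolume
    clean = ImageVolume(const)
    noise = NoiseConfig(photons_high=100.0, exposure_ratio=0.25, read_sigma=0.0)
    rng_h = np.random.default_rng(1)
    rng_l = np.random.default_rng(2)
    high = degrade(clean, noise, "high", rng_h).voxels - const
    low = degrade(clean, noise, "low", rng_l).voxels - const
    ratio = low.std() / high.std()
    assert ratio >= 1.9
    assert ratio == pytest.approx(2.0, rel=0.1)


def test_paired_dataset_properties():
    scene = SceneConfig(volume_shape=SHAPE, n_objects=5)
    noise = NoiseConfig(photons_high=200, exposure_ratio=0.25)
    pairs = make_paired_dataset(scene, noise, 5, master_seed=0)
    assert len(pairs) == 5
    assert all(p.low.shape == p.high.shape == SHAPE for p in pairs)
    # distinct scenes per index
    assert not np.array_equal(pairs[0].high.voxels, pairs[1].high.voxels)
    # deterministic regeneration
    again = make_paired_dataset(scene, noise, 5, master_seed=0)
    assert np.array_equal(pairs[3].low.voxels, again[3].low.voxels)


def test_pair_psnr_decreases_with_exposure_ratio():
    scene = SceneConfig(volume_shape=SHAPE, n_objects=5)
    psnrs = []
    for ratio in (1.0, 0.25, 0.0625):
        noise = NoiseConfig(photons_high=200, exposure_ratio=ratio)
        p = make_paired_dataset(scene, noise, 1, master_seed=4)[0]
        dr = float(p.high.voxels.max() - p.high.voxels.min())
        psnrs.append(psnr(p.low, p.high, dr))
    assert psnrs[0] > psnrs[1] > psnrs[2]


@pytest.fixture(scope="module")
def stack():
    clean = generate_clean_scene(SceneConfig(volume_shape=(4, 64, 64), seed=9,
                                             background=20.0))
    noise = NoiseConfig(photons_high=200, exposure_ratio=0.25, read_sigma=2.0)
    return generate_repeats(clean, noise, n_rep=64, master_seed=21)


def test_repeats_independent_and_unbiased(stack):
    assert stack.n_rep == 64
    assert not np.array_equal(stack.repeats[0], stack.repeats[1])
    mean = stack.repeats.mean(axis=0)
    rel = np.abs(mean - stack.clean.voxels) / stack.clean.voxels.max()
    assert rel.mean() < 0.02
    # residual correlation between two repeats is negligible
    r0 = (stack.repeats[0] - stack.clean.voxels).ravel()
    r1 = (stack.repeats[1] - stack.clean.voxels).ravel()
    assert abs(np.corrcoef(r0, r1)[0, 1]) < 0.05


def test_running_average_ends(stack):
    assert np.array_equal(running_average(stack, 1).voxels, stack.repeats[0])
    assert np.allclose(running_average(stack, 64).voxels,
                       stack.repeats.mean(axis=0), atol=1e-5)
    with pytest.raises(ValueError):
        running_average(stack, 0)
    with pytest.raises(ValueError):
        running_average(stack, 65)


def test_averaging_variance_law(stack):
    """Residual variance of Avg n scales as 1/n."""
    clean = stack.clean.voxels
    var = {n: np.var(running_average(stack, n).voxels - clean)
           for n in (1, 4, 16, 64)}
    for n in (4, 16, 64):
        assert var[n] / var[1] == pytest.approx(1.0 / n, rel=0.15)


def test_config_validation():
    with pytest.raises(ValueError):
        NoiseConfig(exposure_ratio=0.0)
    with pytest.raises(ValueError):
        NoiseConfig(photons_high=-1)
    with pytest.raises(ValueError):
        SceneConfig(psf_sigma=(0, 1, 1))
    with pytest.raises(ValueError):
        generate_repeats(generate_clean_scene(SceneConfig(volume_shape=SHAPE)),
                         NoiseConfig(), n_rep=1)
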