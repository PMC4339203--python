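"""Fractal maps, Hurst regression and the adaptive multifractal descriptor."""

import numpy as np
import pytest

from mnf3d.exceptions import DegenerateProfileError, ParameterError
from mnf3d.fractal import (
    MNFConfig,
    ScaleProfile,
    adaptive_truncation,
    fractal_map,
    hurst_regression,
    mnf_descriptor,
    scale_profile,
    shell_offsets,
    subband_feature,
)
from mnf3d.nakagami import LatticeConfig, NakagamiParametricVolume


def reflect(i, n):
    period = 2 * (n - 1)
    i = i % period
    return period - i if i >= n else i


def bruteforce_profile(volume, center, scales):
    """Naive shell enumeration with mirror indexing."""
    mads = []
    v0 = volume[center]
    for d in range(1, scales + 1):
        vals = []
        for dx in range(-d, d + 1):
            for dy in range(-d, d + 1):
                for dz in range(-d, d + 1):
                    if max(abs(dx), abs(dy), abs(dz)) != d:
                        continue
                    q = (
                        reflect(center[0] + dx, volume.shape[0]),
                        reflect(center[1] + dy, volume.shape[1]),
                        reflect(center[2] + dz, volume.shape[2]),
                    )
                    vals.append(abs(volume[q] - v0))
        mads.append(np.mean(vals))
    return np.array(mads)


def ols_slope_oracle(x, y):
    """Closed-form normal-equations OLS slope and intercept."""
    n = len(x)
    sx, sy = np.sum(x), np.sum(y)
    slope = (np.sum(np.asarray(x) * np.asarray(y)) - sx * sy / n) / (
        np.sum(np.asarray(x) ** 2) - sx**2 / n
    )
    return slope, (sy - slope * sx) / n


class TestScaleProfile:
    def test_constant_volume_zero_increments(self):
        prof = scale_profile(np.full((9, 9, 9), 4.2), (4, 4, 4), scales=3)
        assert np.all(prof.mads == 0)

    def test_ramp_first_shell(self):
        # v = x: on the 26-shell, 18 offsets have |dx|=1 and 8 have dx=0
        n = 11
        vol = np.broadcast_to(np.arange(n, dtype=float)[:, None, None], (n, n, n)).copy()
        prof = scale_profile(vol, (5, 5, 5), scales=2)
        assert prof.mads[0] == pytest.approx(18 / 26, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        vol = rng.normal(size=(16, 16, 16))
        for center in [(8, 8, 8), (0, 0, 0), (15, 3, 12), (2, 14, 1)]:
            prof = scale_profile(vol, center, scales=4)
            want = bruteforce_profile(vol, center, 4)
            assert np.allclose(prof.mads, want, atol=1e-12)
            assert np.array_equal(prof.distances, [1, 2, 3, 4])

    def test_center_outside_volume(self):
        with pytest.raises(ParameterError):
            scale_profile(np.ones((8, 8, 8)), (9, 0, 0), scales=2)


class TestHurstRegression:
    def test_exact_power_law(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        prof = ScaleProfile(d, 1.7 * d**0.7)
        h, intercept = hurst_regression(prof)
        assert h == pytest.approx(0.7, abs=1e-10)
        assert intercept == pytest.approx(np.log(1.7), abs=1e-10)

    def test_flat_profile_gives_zero(self):
        prof = ScaleProfile([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        assert hurst_regression(prof)[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        d = np.arange(1.0, 6.0)
        mads = np.exp(rng.normal(size=5))
        h, b = hurst_regression(ScaleProfile(d, mads))
        hs, bs = ols_slope_oracle(np.log(d), np.log(mads))
        assert h == pytest.approx(hs, abs=1e-12)
        assert b == pytest.approx(bs, abs=1e-12)

    def test_zero_scales_dropped(self):
        prof = ScaleProfile([1.0, 2.0, 3.0, 4.0], [0.0, 2.0 * 2**0.5, 0.0, 2.0 * 4**0.5])
        h, _ = hurst_regression(prof)
        assert h == pytest.approx(0.5, abs=1e-10)

    def test_degenerate_profile(self):
        with pytest.raises(DegenerateProfileError):
            hurst_regression(ScaleProfile([1.0, 2.0], [0.0, 0.0]))


class TestFractalMap:
    def test_constant_volume_is_dimension_two(self):
        fm = fractal_map(np.full((12, 12, 12), 3.3), scales=3)
        assert np.allclose(fm.fd_map, 2.0)
        assert np.allclose(fm.hurst_map, 1.0)

    def test_affine_invariance(self, rng):
        vol = rng.normal(size=(14, 14, 14)) ** 2
        base = fractal_map(vol, scales=3)
        trans = fractal_map(3.7 * vol + 12.0, scales=3)
        assert np.allclose(base.fd_map, trans.fd_map, atol=1e-9, equal_nan=True)

    def test_matches_per_voxel_bruteforce(self, rng):
        vol = rng.normal(size=(10, 10, 10))
        fm = fractal_map(vol, scales=3)
        for center in [(0, 0, 0), (5, 5, 5), (9, 2, 7)]:
            mads = bruteforce_profile(vol, center, 3)
            keep = mads > 0
            slope, _ = ols_slope_oracle(np.log(np.arange(1, 4)[keep]), np.log(mads[keep]))
            expected = 3.0 - np.clip(slope, 0.0, 1.0)
            assert fm.fd_map[center] == pytest.approx(expected, abs=1e-10)

    def test_masked_region_only(self, rng):
        vol = rng.normal(size=(12, 12, 12))
        mask = np.zeros(vol.shape, dtype=bool)
        mask[3:8, 3:8, 3:8] = True
        fm = fractal_map(vol, mask, scales=3)
        assert np.isnan(fm.fd_map[0, 0, 0])
        assert np.isfinite(fm.fd_map[mask]).all()
        # masked computation agrees with the unmasked one
        full = fractal_map(vol, scales=3)
        assert np.allclose(fm.fd_map[mask], full.fd_map[mask], atol=1e-12)

    def test_fbm_roughness_monotone_in_hurst(self):
        from mnf3d.synthetic import make_fbm_volume

        means = []
        for h in (0.2, 0.5, 0.8):
            vol = make_fbm_volume(h, 32, seed=10)
            fm = fractal_map(vol.data, scales=4)
            means.append(np.nanmean(fm.fd_map))
        assert means[0] > means[1] > means[2]  # I = 3 - H

    def test_empty_roi(self):
        with pytest.raises(ParameterError):
            fractal_map(np.ones((8, 8, 8)), np.zeros((8, 8, 8), dtype=bool))


class TestSubbandFeature:
    def test_constant_map(self):
        fm = fractal_map(np.full((10, 10, 10), 1.0), scales=2)
        assert subband_feature(fm) == pytest.approx(2.0)

    def test_mean_over_valid_subset(self, rng):
        vol = rng.normal(size=(12, 12, 12))
        mask = rng.random((12, 12, 12)) > 0.5
        fm = fractal_map(vol, mask, scales=3)
        acc, cnt = 0.0, 0
        for idx in np.ndindex(vol.shape):
            if mask[idx] and np.isfinite(fm.fd_map[idx]):
                acc += fm.fd_map[idx]
                cnt += 1
        assert subband_feature(fm) == pytest.approx(acc / cnt, abs=1e-12)


class TestAdaptiveTruncation:
    @staticmethod
    def _blocks_for_trace():
        # level 1: adjacent-band differences max 0.20; level 2: max 0.05
        lvl1 = np.array([2.5, 2.3, 2.4, 2.45, 2.5, 2.42, 2.38, 2.4])
        lvl2 = np.array([2.5, 2.45, 2.48, 2.5, 2.47, 2.46, 2.44, 2.43])
        return {1: lvl1, 2: lvl2}

    def test_termination_trace(self):
        blocks = self._blocks_for_trace()
        levels = []

        def level_fn(i):
            levels.append(i)
            return [blocks[i], blocks[i]]

        out_blocks, trace, used, terminated = adaptive_truncation(level_fn, max_levels=3)
        assert used == 2 and terminated
        assert trace == pytest.approx([0.20, 0.05])
        assert levels == [1, 2]  # level 3 never computed
        feats = np.concatenate([np.concatenate(b) for b in out_blocks])
        assert feats.size == 2 * 8 * used

    def test_no_termination_flag(self):
        rising = {1: np.linspace(2.0, 2.07, 8), 2: np.linspace(2.0, 2.3, 8),
                  3: np.linspace(2.0, 2.8, 8)}

        def level_fn(i):
            return [rising[i]]

        _, trace, used, terminated = adaptive_truncation(level_fn, max_levels=3)
        assert used == 3 and not terminated
        assert trace[0] < trace[1] < trace[2]


def _toy_parametric_volume(rng, n=20):
    mu = np.abs(rng.normal(loc=1.0, scale=0.2, size=(n, n, n))) + 0.1
    omega = np.abs(rng.normal(loc=2.0, scale=0.5, size=(n, n, n))) + 0.1
    return NakagamiParametricVolume(mu, omega, np.ones((n, n, n), dtype=bool), LatticeConfig())


class TestMnfDescriptor:
    def test_feature_count_and_range(self, rng):
        pv = _toy_parametric_volume(rng)
        desc = mnf_descriptor(pv, config=MNFConfig(scales=3, max_levels=2))
        assert desc.features.size == 2 * 8 * desc.levels_used
        assert np.all(desc.features >= 2.0) and np.all(desc.features <= 3.0)
        assert desc.threshold_trace.size == desc.levels_used

    def test_affine_invariance_of_descriptor(self, rng):
        pv = _toy_parametric_volume(rng)
        scaled = NakagamiParametricVolume(
            3.7 * pv.mu_map + 12.0, 3.7 * pv.omega_map + 12.0,
            pv.valid_mask, pv.lattice_config,
        )
        d1 = mnf_descriptor(pv, config=MNFConfig(scales=3, max_levels=2))
        d2 = mnf_descriptor(scaled, config=MNFConfig(scales=3, max_levels=2))
        assert d1.levels_used == d2.levels_used
        assert np.allclose(d1.features, d2.features, atol=1e-8)

    def test_determinism(self, rng):
        pv = _toy_parametric_volume(rng)
        cfg = MNFConfig(scales=3, max_levels=2)
        d1 = mnf_descriptor(pv, config=cfg)
        d2 = mnf_descriptor(pv, config=cfg)
        assert np.array_equal(d1.features, d2.features)
        assert d1.levels_used == d2.levels_used


def test_shell_offsets_counts():
    # Chebyshev shell sizes: (2d+1)^3 - (2d-1)^3
    for d, count in [(1, 26), (2, 98), (3, 218), (4, 386)]:
        offs = shell_offsets(d)
        assert offs.shape == (count, 3)
        assert (np.abs(offs).max(axis=1) == d).all()
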