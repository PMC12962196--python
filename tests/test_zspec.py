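"""Z-spectrum forward model, normalisation, baseline removal, five-pool fit."""

import numpy as np
import pytest

from cordmap import zspec
from cordmap.protocols import ProtocolError, ZspecProtocol


def pools_with(**amplitudes):
    """Default pool table with amplitudes overridden by short name (DS, CEST35...)."""
    short = {"CEST3.5": "A_CEST35", "CEST2.0": "A_CEST20", "DS": "A_DS",
             "NOE1.6": "A_NOE16", "NOE3.5": "A_NOE35"}
    return [
        zspec.LorentzianPool(p.name, amplitudes.get(short[p.name], p.amplitude),
                             p.width_ppm)
        for p in zspec.default_pool_table()
    ]


class TestForward:
    def test_no_pools_no_baseline_is_unity(self, zspec_protocol):
        pools = [zspec.LorentzianPool(n, 0.0, 1.0) for n in zspec.POOL_NAMES]
        assert np.allclose(zspec.zspectrum_forward(pools, 0.0, zspec_protocol), 1.0)

    def test_lorentzian_half_maximum_at_half_width(self, zspec_protocol):
        # single DS pool A=0.8, FWHM 1.0: Z(0)=0.2 and Z(+-w/2)=0.6
        pools = [zspec.LorentzianPool("DS", 0.8, 1.0)] + [
            zspec.LorentzianPool(n, 0.0, 1.0) for n in zspec.POOL_NAMES if n != "DS"]
        z = zspec.zspectrum_forward(pools, 0.0, zspec_protocol)
        offs = zspec_protocol.offsets_ppm
        assert z[np.isclose(offs, 0.0)][0] == pytest.approx(0.2)
        for hw in (-0.5, 0.5):  # half-width points, off the 0.2 ppm grid
            assert 1.0 - zspec.pools_sum(np.array([hw]), pools)[0] == \
                pytest.approx(1 - 0.8 / 2)

    def test_default_pool_table_minimum_at_water_resonance(self, zspec_protocol):
        z = zspec.zspectrum_forward(zspec.default_pool_table(), 0.08, zspec_protocol)
        assert np.isclose(zspec_protocol.offsets_ppm[np.argmin(z)], 0.0)

    def test_nonphysical_totals_rejected(self, zspec_protocol):
        pools = pools_with(A_DS=0.99)
        with pytest.raises(ValueError, match="nonphysical"):
            zspec.zspectrum_forward(pools, 0.1, zspec_protocol)


class TestNormalize:
    def test_half_signal_gives_half_z(self, zspec_protocol):
        n = zspec_protocol.n_volumes
        stack = np.full((2, 2, 1, n), 50.0)
        stack[..., 0] = stack[..., -1] = 100.0
        z, clip = zspec.normalize_zspectrum(stack, zspec_protocol)
        assert np.allclose(z, 0.5)
        assert not clip.any()

    def test_drift_interpolation_uses_midpoint_divisor(self, zspec_protocol):
        n = zspec_protocol.n_offsets
        stack = np.ones((1, 1, 1, n + 2))
        stack[..., 0], stack[..., -1] = 1.0, 0.9
        z, _ = zspec.normalize_zspectrum(stack, zspec_protocol)
        mid = (n - 1) // 2  # sample 26 of 51: mid-acquisition
        assert z[0, 0, 0, mid] == pytest.approx(1.0 / 0.95)

    def test_driftfree_interp_and_mean_agree(self, zspec_protocol, rng):
        n = zspec_protocol.n_volumes
        sat = rng.uniform(0.3, 1.0, (3, 3, 1, n - 2))
        stack = np.concatenate(
            [np.full((3, 3, 1, 1), 2.0), 2.0 * sat, np.full((3, 3, 1, 1), 2.0)],
            axis=-1)
        z1, _ = zspec.normalize_zspectrum(stack, zspec_protocol, mode="interp")
        z2, _ = zspec.normalize_zspectrum(stack, zspec_protocol, mode="mean")
        assert np.abs(z1 - z2).max() < 1e-12

    def test_nonpositive_reference_masks_voxel(self, zspec_protocol):
        stack = np.ones((2, 1, 1, zspec_protocol.n_volumes))
        stack[0, 0, 0, 0] = 0.0
        z, _ = zspec.normalize_zspectrum(stack, zspec_protocol)
        assert np.isnan(z[0]).all() and np.isfinite(z[1]).all()


class TestInvertAndDebase:
    def test_unity_spectrum_maps_to_zero(self, zspec_protocol):
        y = zspec.invert_and_debase(np.ones(zspec_protocol.n_offsets), zspec_protocol)
        assert np.allclose(y, 0.0)

    def test_anchor_is_exactly_zero_and_baseline_invariant(self, zspec_protocol, rng):
        z = rng.uniform(0.2, 0.9, zspec_protocol.n_offsets)
        y1 = zspec.invert_and_debase(z, zspec_protocol)
        y2 = zspec.invert_and_debase(z - 0.07, zspec_protocol)  # constant shift
        anchor = np.argmax(zspec_protocol.offsets_ppm)
        assert y1[anchor] == 0.0
        assert np.allclose(y1, y2)

    def test_recovers_pool_sum_up_to_endpoint_tail(self, zspec_protocol):
        pools = zspec.default_pool_table()
        z = zspec.zspectrum_forward(pools, 0.08, zspec_protocol)
        y = zspec.invert_and_debase(z, zspec_protocol)
        l_sum = zspec.pools_sum(zspec_protocol.offsets_ppm, pools)
        tail = zspec.pools_sum(np.array([5.0]), pools)[0]
        assert np.abs(y - l_sum).max() <= tail + 1e-12

    def test_missing_anchor_sample_raises(self):
        protocol = ZspecProtocol(offsets_ppm=np.arange(-4.0, 4.01, 0.2))
        with pytest.raises(ProtocolError, match="anchor"):
            zspec.invert_and_debase(np.ones(protocol.n_offsets), protocol)


class TestFitFivePool:
    def test_noiseless_roundtrip_within_2pct(self, zspec_protocol):
        pools = zspec.default_pool_table()
        z = zspec.zspectrum_forward(pools, 0.08, zspec_protocol)
        fit = zspec.fit_five_pool(zspec.invert_and_debase(z, zspec_protocol),
                                  zspec_protocol)
        for p in pools:
            assert fit.amplitude(p.name) == pytest.approx(p.amplitude, rel=0.02)

    def test_absent_peak_fits_to_near_zero(self, zspec_protocol):
        pools = pools_with(A_CEST35=0.0)
        z = zspec.zspectrum_forward(pools, 0.05, zspec_protocol)
        fit = zspec.fit_five_pool(zspec.invert_and_debase(z, zspec_protocol),
                                  zspec_protocol)
        assert fit.amplitude("CEST3.5") <= 0.005

    def test_rerun_is_bit_identical(self, zspec_protocol, rng):
        z = zspec.zspectrum_forward(zspec.default_pool_table(), 0.08, zspec_protocol)
        y = zspec.invert_and_debase(z + rng.normal(0, 0.005, z.size), zspec_protocol)
        f1 = zspec.fit_five_pool(y, zspec_protocol)
        f2 = zspec.fit_five_pool(y, zspec_protocol)
        assert f1.as_dict() == f2.as_dict()

    def test_noe16_mean_recovery_under_noise(self, zspec_protocol):
        # Gaussian noise SD 0.005 on Z, 200 replicates: mean within 10%
        rng = np.random.default_rng(21)
        z0 = zspec.zspectrum_forward(zspec.default_pool_table(), 0.08, zspec_protocol)
        amps = []
        for _ in range(200):
            z = z0 + rng.normal(0, 0.005, z0.size)
            fit = zspec.fit_five_pool(zspec.invert_and_debase(z, zspec_protocol),
                                      zspec_protocol)
            amps.append(fit.amplitude("NOE1.6"))
        assert np.mean(amps) == pytest.approx(0.04, rel=0.10)

    def test_amplitude_rmse_monotone_in_noise(self, zspec_protocol):
        rng = np.random.default_rng(3)
        z0 = zspec.zspectrum_forward(zspec.default_pool_table(), 0.08, zspec_protocol)
        truth = np.array([p.amplitude for p in zspec.default_pool_table()])
        rmses = []
        for sd in (0.002, 0.005, 0.01):
            errs = []
            for _ in range(40):
                z = z0 + rng.normal(0, sd, z0.size)
                fit = zspec.fit_five_pool(
                    zspec.invert_and_debase(z, zspec_protocol), zspec_protocol)
                est = np.array([fit.amplitude(p.name)
                                for p in zspec.default_pool_table()])
                errs.append(est - truth)
            rmses.append(np.sqrt(np.mean(np.square(errs))))
        assert rmses[0] < rmses[1] < rmses[2]

    def test_pool_center_value_equals_amplitude(self, zspec_protocol):
        # definition check: lone pool evaluated at its center gives A
        for name in zspec.POOL_NAMES:
            val = zspec.lorentzian(np.array([zspec.POOL_CENTERS_PPM[name]]),
                                   0.3, 1.7, zspec.POOL_CENTERS_PPM[name])
            assert val[0] == pytest.approx(0.3, abs=1e-15)
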