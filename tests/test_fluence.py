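"""Forward-engine oracles: Beer-Lambert, analytic diffusion, energy
conservation, and cross-backend consistency."""

import numpy as np
import pytest
from scipy.special import k0

from milsd.fluence import (
    IlluminationGeometry,
    diffusion_fluence,
    mc_fluence,
    simulate_stack,
)
from milsd.phantoms import SamplerConfig, TubeSpec, rasterize_optics, \
    sample_training_volume
from milsd.spectra import ChromophoreMixture, WavelengthGrid

GRID1 = WavelengthGrid((800.0,))
BG0 = ChromophoreMixture(0.0, 0.0, "sulfate")


def homogeneous_phantom(mu_a, mu_sp, extent=(60.0, 40.0), pitch=0.2):
    ph = rasterize_optics([], BG0, grid=GRID1, extent_mm=extent, pitch_mm=pitch)
    ph.mu_a[:] = mu_a
    ph.mu_s_prime[:] = mu_sp
    return ph


def analytic_line_source_fluence(ph, mu_a, mu_sp, x0_cm):
    """Independent closed form: semi-infinite medium, line source one
    transport mfp deep, extrapolated-boundary image source (K0 kernel)."""
    D = 1.0 / (3.0 * (mu_a + mu_sp))
    mueff = np.sqrt(mu_a / D)
    z0 = 1.0 / (mu_a + mu_sp)
    zb = 2.0 * D
    h = ph.pitch_mm / 10.0
    nz, nx = ph.shape
    zc = (np.arange(nz) + 0.5) * h
    xc = (np.arange(nx) + 0.5) * h
    XX, ZZ = np.meshgrid(xc, zc)
    r1 = np.sqrt((XX - x0_cm) ** 2 + (ZZ - z0) ** 2)
    r2 = np.sqrt((XX - x0_cm) ** 2 + (ZZ + z0 + 2 * zb) ** 2)
    phi = (k0(mueff * np.maximum(r1, 1e-9)) - k0(mueff * r2)) / (2 * np.pi * D)
    return phi, r1, ZZ, z0


class TestMonteCarlo:
    def test_beer_lambert_in_pure_absorber(self):
        # pencil beam into mu_a = 1/cm, mu_s' = 0: on-axis fluence decays
        # as exp(-mu_a z); agreement within 3 sigma of MC error at 10 depths
        mu_a = 1.0
        n = 1_000_000
        ph = homogeneous_phantom(mu_a, 0.0, extent=(20.0, 20.0), pitch=0.2)
        il = IlluminationGeometry(n_positions=1, beam_fwhm_mm=0.0)
        phi = mc_fluence(ph, il, 0, 0, n_photons=n, rng_state=7, g=0.0)
        h = 0.02
        col = phi[:, ph.shape[1] // 2]
        zc = (np.arange(ph.shape[0]) + 0.5) * h
        for iz in range(2, 52, 5):  # 10 depths, 0.5-10 mm
            p = np.exp(-mu_a * zc[iz])
            expect = p / h
            sigma = np.sqrt(p * (1 - p) / n) / h  # binomial passage statistics
            assert abs(col[iz] - expect) <= 3.0 * sigma + 1e-12

    def test_energy_conservation_with_roulette(self):
        ph = homogeneous_phantom(0.5, 10.0, extent=(20.0, 20.0), pitch=0.4)
        il = IlluminationGeometry(n_positions=1, beam_fwhm_mm=2.0)
        res = mc_fluence(ph, il, 0, 0, n_photons=20_000, rng_state=3, g=0.0,
                         return_ledger=True)
        balance = res.absorbed + res.escaped - res.roulette_net - res.launched
        assert abs(balance) / res.launched < 1e-6
        assert np.all(res.fluence >= 0) and np.all(np.isfinite(res.fluence))

    def test_matches_analytic_diffusion_in_high_albedo_medium(self):
        mu_a, mu_sp = 0.1, 15.0
        ph = homogeneous_phantom(mu_a, mu_sp)
        il = IlluminationGeometry(n_positions=1, beam_fwhm_mm=0.0)
        phi = mc_fluence(ph, il, 0, 0, n_photons=300_000, rng_state=3, g=0.0)
        an, r1, ZZ, z0 = analytic_line_source_fluence(ph, mu_a, mu_sp, 3.0)
        for r_mm in (5.0, 7.5, 10.0, 12.5, 15.0):
            ring = (np.abs(r1 - r_mm / 10.0) < 0.05) & (ZZ > z0)
            ratio = phi[ring].mean() / an[ring].mean()
            assert abs(ratio - 1.0) < 0.15

    def test_deterministic_under_fixed_seed(self):
        ph = homogeneous_phantom(0.2, 5.0, extent=(10.0, 10.0), pitch=0.5)
        il = IlluminationGeometry(n_positions=1)
        a = mc_fluence(ph, il, 0, 0, n_photons=5_000, rng_state=11)
        b = mc_fluence(ph, il, 0, 0, n_photons=5_000, rng_state=11)
        assert np.array_equal(a, b)

    def test_transparent_medium_is_valid(self):
        ph = homogeneous_phantom(0.0, 0.0, extent=(10.0, 10.0), pitch=0.5)
        il = IlluminationGeometry(n_positions=1, beam_fwhm_mm=0.0)
        res = mc_fluence(ph, il, 0, 0, n_photons=2_000, rng_state=1, g=0.0,
                         return_ledger=True)
        # ballistic fluence along the beam, everything escapes
        assert res.escaped == pytest.approx(res.launched)
        assert res.fluence.max() > 0

    def test_invalid_inputs_rejected(self):
        ph = homogeneous_phantom(0.1, 1.0, extent=(10.0, 10.0), pitch=0.5)
        il = IlluminationGeometry(n_positions=1)
        with pytest.raises(ValueError):
            mc_fluence(ph, il, 0, 0, n_photons=0)


class TestDiffusion:
    def test_matches_analytic_semi_infinite_solution(self):
        mu_a, mu_sp = 0.1, 15.0
        ph = homogeneous_phantom(mu_a, mu_sp)
        il = IlluminationGeometry(n_positions=1, beam_fwhm_mm=0.0)
        phi = diffusion_fluence(ph, il, 0, 0)
        an, r1, ZZ, z0 = analytic_line_source_fluence(ph, mu_a, mu_sp, 3.0)
        for r_mm in (5.0, 7.5, 10.0, 12.5, 15.0):
            ring = (np.abs(r1 - r_mm / 10.0) < 0.05) & (ZZ > z0)
            ratio = phi[ring].mean() / an[ring].mean()
            assert abs(ratio - 1.0) < 0.10

    def test_doubling_absorption_decreases_fluence_at_depth(self):
        il = IlluminationGeometry(n_positions=1)
        ph1 = homogeneous_phantom(0.05, 10.0, extent=(30.0, 20.0), pitch=0.25)
        ph2 = homogeneous_phantom(0.10, 10.0, extent=(30.0, 20.0), pitch=0.25)
        a = diffusion_fluence(ph1, il, 0, 0)
        b = diffusion_fluence(ph2, il, 0, 0)
        deep = slice(int(2.0 / 0.25), None)  # below 2 mm
        assert np.all(b[deep] < a[deep])

    def test_deterministic(self):
        ph = sample_training_volume(SamplerConfig(), 4, grid=GRID1)
        il = IlluminationGeometry()
        a = diffusion_fluence(ph, il, 1, 0)
        b = diffusion_fluence(ph, il, 1, 0)
        assert np.array_equal(a, b)

    def test_cross_backend_agreement_at_tube_locations(self):
        # heterogeneous instance: MC and FD diffusion agree at tubes
        # deeper than 2 mm
        grid = GRID1
        tubes = [TubeSpec((15.0, 4.0), 0.4, 0.8), TubeSpec((15.0, 8.0), 0.4, 0.2)]
        ph = rasterize_optics(tubes, ChromophoreMixture(0.5, 0.01), grid=grid,
                              extent_mm=(30.0, 20.0), pitch_mm=0.25)
        il = IlluminationGeometry(n_positions=1)
        fd = diffusion_fluence(ph, il, 0, 0)
        mc = mc_fluence(ph, il, 0, 0, n_photons=400_000, rng_state=5, g=0.0)
        for tube_id in (1, 2):
            m = ph.labels == tube_id
            ratio = mc[m].mean() / fd[m].mean()
            assert abs(ratio - 1.0) < 0.15

    def test_zero_transport_medium_rejected(self):
        ph = homogeneous_phantom(0.0, 0.0, extent=(10.0, 10.0), pitch=0.5)
        il = IlluminationGeometry(n_positions=1)
        with pytest.raises(ValueError):
            diffusion_fluence(ph, il, 0, 0)


class TestStack:
    def test_default_sequence_has_64_maps(self):
        ph = sample_training_volume(SamplerConfig(), 2)
        stack = simulate_stack(ph, IlluminationGeometry(), backend="diffusion")
        assert stack.H.shape[:2] == (4, 16)
        assert np.all(stack.H >= 0)

    def test_h_is_fluence_times_absorption_pointwise(self):
        ph = sample_training_volume(SamplerConfig(), 2, grid=GRID1)
        il = IlluminationGeometry()
        stack = simulate_stack(ph, il, backend="diffusion")
        phi = diffusion_fluence(ph, il, 2, 0)
        assert np.allclose(stack.H[2, 0], phi * ph.mu_a[0])

    def test_tube_brighter_under_nearest_illumination(self):
        # a tube directly below beam 0 receives more energy than from
        # the farthest beam
        il = IlluminationGeometry()
        x_beam0 = il.beam_centers_mm(40.0)[0]
        tubes = [TubeSpec((x_beam0, 6.0), 0.4, 0.5)]
        ph = rasterize_optics(tubes, ChromophoreMixture(0.5, 0.02),
                              grid=WavelengthGrid((680.0, 980.0)))
        stack = simulate_stack(ph, il, backend="diffusion")
        m = ph.labels == 1
        for wl in range(2):
            assert stack.H[0, wl][m].mean() > stack.H[3, wl][m].mean()

    def test_spectral_coloring_grows_with_background_absorption(self):
        # deep tube: normalized H spectrum deviates from normalized mu_a
        # spectrum, and more so for a denser background
        grid = WavelengthGrid(tuple(np.arange(680.0, 981.0, 60.0)))
        il = IlluminationGeometry()
        dists = []
        for vf in (0.005, 0.03):
            tubes = [TubeSpec((20.0, 8.0), 0.4, 0.7)]
            ph = rasterize_optics(tubes, ChromophoreMixture(0.3, vf), grid=grid)
            stack = simulate_stack(ph, il, backend="diffusion")
            m = ph.labels == 1
            spec = stack.H[:, :, m].mean(axis=(0, 2))
            mua = ph.mu_a[:, m].mean(axis=1)
            dists.append(np.abs(spec / spec.sum() - mua / mua.sum()).sum())
        assert dists[0] > 0
        assert dists[1] > dists[0]

    def test_mc_backend_stack_smoke(self):
        ph = sample_training_volume(
            SamplerConfig(extent_mm=(20.0, 12.0), depth_bounds_mm=(2.0, 8.0)),
            3, grid=GRID1)
        stack = simulate_stack(ph, IlluminationGeometry(n_positions=2),
                               backend="mc", n_photons=20_000, seed=9)
        assert stack.H.shape[:2] == (2, 1)
        assert np.all(stack.H >= 0) and stack.H.max() > 0
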