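"""Normal-mode analysis, tensor invariants, stick intensities,
lineshape convolution and snapshot averaging."""

import numpy as np
import pytest

from collagen_roa.geometry import Geometry, GeometryError
from collagen_roa.spectra import (
    EXCITATION_CM,
    FREQ_CONV,
    SpectrumPair,
    StickSpectrum,
    average_snapshots,
    backscatter_sticks,
    boltzmann_factor,
    convolve,
    default_grid,
    mode_invariants,
    normal_modes,
    read_spectrum,
    spectrum_from_tensors,
    subspace_optimize,
    write_spectrum,
)
from collagen_roa.synthetic import make_chiral_tensors, make_spring_system
from collagen_roa.transfer import PropertyTensorSet

from conftest import random_rotation


class TestNormalModes:
    def test_diatomic_closed_form(self):
        geom, H = make_spring_system(2, k=1.0, masses=[1.0, 1.0], kind="chain")
        modes = normal_modes(geom, H)
        # reduced mass 1/2 -> omega = sqrt(2 k / m)
        assert modes.frequencies[-1] == pytest.approx(
            np.sqrt(2.0) * FREQ_CONV, rel=1e-8
        )
        assert modes.n_projected == 5  # linear molecule

    def test_rigid_body_modes_projected_out(self, spring_network):
        geom, H = spring_network
        modes = normal_modes(geom, H)
        assert modes.n_projected == 6
        assert modes.n_modes == 3 * geom.n_atoms - 6
        # remaining spectrum contains no near-zero rigid leftovers
        assert np.abs(modes.frequencies).min() > 1.0

    def test_mode_vectors_orthonormal(self, spring_network):
        geom, H = spring_network
        modes = normal_modes(geom, H)
        Q = modes.displacements.reshape(modes.n_modes, -1)
        assert np.abs(Q @ Q.T - np.eye(modes.n_modes)).max() < 1e-8

    def test_frequencies_match_unprojected_eigensolver(self):
        """Independent oracle: diagonalize the mass-weighted Hessian
        without any Eckart machinery and drop the six rigid roots."""
        for seed in range(3):
            geom, H = make_spring_system(5, k=1.3, seed=seed, kind="network")
            modes = normal_modes(geom, H)
            isq = 1.0 / np.sqrt(np.repeat(geom.masses, 3))
            lam = np.linalg.eigvalsh(H * isq[:, None] * isq[None, :])
            oracle = np.sqrt(np.abs(lam[6:])) * FREQ_CONV  # rigid roots are smallest
            assert np.abs(modes.frequencies - oracle).max() < 1e-6 * oracle.max()

    def test_asymmetric_hessian_rejected(self, spring_network):
        geom, H = spring_network
        bad = H.copy()
        bad[0, 1] += 1.0
        with pytest.raises(GeometryError):
            normal_modes(geom, bad)

    def test_rotational_invariance_of_spectrum(self, small_helix, helix_tensors):
        rng = np.random.default_rng(17)
        R = random_rotation(rng)
        rotated = small_helix.with_coords(small_helix.coords @ R.T)
        f0 = normal_modes(small_helix, helix_tensors.hessian).frequencies
        f1 = normal_modes(rotated, helix_tensors.rotated(R).hessian).frequencies
        assert np.abs(f0 - f1).max() < 1e-6
        p0 = spectrum_from_tensors(small_helix, helix_tensors)
        p1 = spectrum_from_tensors(rotated, helix_tensors.rotated(R))
        assert np.abs(p0.raman - p1.raman).max() < 1e-8 * p0.raman.max()
        assert np.abs(p0.roa - p1.roa).max() < 1e-8 * np.abs(p0.roa).max()


class TestSubspaceOptimize:
    def test_quadratic_surface_single_newton_step(self, spring_network):
        geom, H = spring_network
        x_min = geom.coords + 0.0  # expand around a shifted quadratic minimum
        shift = 0.02 * np.random.default_rng(1).standard_normal(geom.coords.shape)
        x_min = geom.coords + shift

        def quad(coords):
            d = (coords - x_min).ravel()
            return 0.5 * d @ H @ d, (H @ d).reshape(-1, 3)

        out = subspace_optimize(geom, quad, H, freq_window=(0.0, 1.0e6), max_iter=1)
        _, g = quad(out.coords)
        assert np.abs(g).max() < 1e-8

    def test_full_window_reaches_anharmonic_minimum(self, spring_network):
        geom, H = spring_network
        x_min = geom.coords + 0.01

        def quartic(coords):
            d = (coords - x_min).ravel()
            e = 0.5 * d @ H @ d + 0.05 * (d**4).sum()
            g = H @ d + 0.2 * d**3
            return e, g.reshape(-1, 3)

        out = subspace_optimize(geom, quartic, H, freq_window=(0.0, 1.0e6))
        _, g = quartic(out.coords)
        # full minimization over every internal coordinate: the gradient
        # projected on the (rigid-free) mode space vanishes
        modes = normal_modes(geom, H)
        D = modes.displacements.reshape(modes.n_modes, -1) / np.sqrt(
            np.repeat(geom.masses, 3)
        )
        assert np.abs(D @ g.ravel()).max() < 1e-8

    def test_frozen_modes_unchanged(self, spring_network):
        geom, H = spring_network
        modes = normal_modes(geom, H)
        cutoff = np.median(modes.frequencies)
        x_min = geom.coords + 0.015

        def quartic(coords):
            d = (coords - x_min).ravel()
            return 0.5 * d @ H @ d + 0.02 * (d**4).sum(), (
                H @ d + 0.08 * d**3
            ).reshape(-1, 3)

        out = subspace_optimize(geom, quartic, H, freq_window=(cutoff, 1.0e6))
        frozen = modes.frequencies < cutoff
        Qf = modes.displacements[frozen].reshape(frozen.sum(), -1)
        disp_mw = (out.coords - geom.coords).ravel() * np.sqrt(
            np.repeat(geom.masses, 3)
        )
        assert np.abs(Qf @ disp_mw).max() < 1e-6


def achiral_planar_system(n=6, seed=2):
    """Planar geometry with tensors symmetrized under the z-reflection:
    an achiral system by construction."""
    from collagen_roa.transfer import mirror_image

    rng = np.random.default_rng(seed)
    coords = np.column_stack(
        [1.4 * np.arange(n), 0.3 * rng.standard_normal(n), np.zeros(n)]
    )
    geom = Geometry(
        elements=np.array(["C"] * n, dtype=object), coords=coords
    )
    ts = make_chiral_tensors(geom, roa_scale=1.0e-3, seed=seed)
    _, ts_m = mirror_image(geom, ts)  # z -> -z maps the geometry onto itself
    sym = PropertyTensorSet(
        hessian=0.5 * (ts.hessian + ts_m.hessian),
        dipole_deriv=0.5 * (ts.dipole_deriv + ts_m.dipole_deriv),
        alpha_deriv=0.5 * (ts.alpha_deriv + ts_m.alpha_deriv),
        gprime_deriv=0.5 * (ts.gprime_deriv + ts_m.gprime_deriv),
        a_deriv=0.5 * (ts.a_deriv + ts_m.a_deriv),
    )
    return geom, sym


class TestInvariants:
    def test_isotropic_alpha_has_zero_anisotropy(self, spring_network):
        geom, H = spring_network
        modes = normal_modes(geom, H)
        n = geom.n_atoms
        ts = PropertyTensorSet(
            hessian=H,
            dipole_deriv=np.zeros((n, 3, 3)),
            alpha_deriv=np.einsum(
                "ij,ab->aijb", np.eye(3), np.ones((n, 3))
            ),  # alpha = c * I for every displacement
            gprime_deriv=np.zeros((n, 3, 3, 3)),
            a_deriv=np.zeros((n, 3, 3, 3, 3)),
        )
        inv = mode_invariants(modes, ts)
        assert np.abs(inv["beta_alpha2"]).max() < 1e-10 * max(inv["a2"].max(), 1.0)
        assert np.all(inv["beta_g2"] == 0.0)
        assert np.all(inv["beta_a2"] == 0.0)

    def test_achiral_planar_tensors_have_no_chiral_invariants(self):
        geom, ts = achiral_planar_system()
        modes = normal_modes(geom, ts.hessian)
        inv = mode_invariants(modes, ts)
        scale = max(inv["beta_alpha2"].max(), 1.0)
        assert np.abs(inv["beta_g2"]).max() < 1e-10 * scale
        assert np.abs(inv["beta_a2"]).max() < 1e-10 * scale

    def test_invariants_match_levi_civita_loop_oracle(self, small_helix, helix_tensors):
        modes = normal_modes(small_helix, helix_tensors.hessian)
        inv = mode_invariants(modes, helix_tensors)
        disp = modes.cartesian_displacements()
        eps = np.zeros((3, 3, 3))
        for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            eps[i, j, k] = 1.0
            eps[k, j, i] = -1.0
        omega = EXCITATION_CM / 219474.6313632
        for p in (0, modes.n_modes // 2, modes.n_modes - 1):
            alpha = np.zeros((3, 3))
            gp = np.zeros((3, 3))
            at = np.zeros((3, 3, 3))
            for a in range(small_helix.n_atoms):
                for b in range(3):
                    alpha += helix_tensors.alpha_deriv[a, :, :, b] * disp[p, a, b]
                    gp += helix_tensors.gprime_deriv[a, :, :, b] * disp[p, a, b]
                    at += helix_tensors.a_deriv[a, :, :, :, b] * disp[p, a, b]
            tr = np.trace(alpha)
            assert inv["a2"][p] == pytest.approx((tr / 3.0) ** 2, abs=1e-12)
            assert inv["beta_alpha2"][p] == pytest.approx(
                0.5 * (3.0 * (alpha * alpha).sum() - tr**2), rel=1e-12, abs=1e-12
            )
            assert inv["beta_g2"][p] == pytest.approx(
                0.5 * (3.0 * (alpha * gp).sum() - tr * np.trace(gp)),
                rel=1e-12, abs=1e-12,
            )
            oracle_ba = 0.0
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        for l in range(3):
                            oracle_ba += alpha[i, j] * eps[i, k, l] * at[k, l, j]
            assert inv["beta_a2"][p] == pytest.approx(
                0.5 * omega * oracle_ba, rel=1e-12, abs=1e-12
            )


class TestSticks:
    def test_boltzmann_factor_low_temperature_limit(self):
        assert abs(boltzmann_factor(np.array([1000.0]), 1.0)[0] - 1.0) < 1e-20
        assert np.all(boltzmann_factor(np.array([100.0, 1000.0]), 0.0) == 1.0)

    def test_boltzmann_factor_grows_with_temperature(self):
        f300 = boltzmann_factor(np.array([300.0]), 300.0)[0]
        assert f300 > 1.0

    def test_achiral_set_gives_zero_roa_sticks(self):
        geom, ts = achiral_planar_system()
        modes = normal_modes(geom, ts.hessian)
        sticks = backscatter_sticks(modes, mode_invariants(modes, ts))
        assert np.abs(sticks.roa).max() < 1e-10 * sticks.raman.max()
        assert sticks.raman.max() > 0.0

    def test_physical_scaling_keeps_cid_regime(self, small_helix, helix_tensors):
        modes = normal_modes(small_helix, helix_tensors.hessian)
        sticks = backscatter_sticks(modes, mode_invariants(modes, helix_tensors))
        ratio = np.abs(sticks.roa) / sticks.raman
        assert 1.0e-4 <= ratio.max() <= 1.0e-2

    def test_excitation_below_modes_rejected(self, spring_network):
        geom, H = spring_network
        modes = normal_modes(geom, H)
        with pytest.raises(ValueError):
            backscatter_sticks(modes, mode_invariants(modes, _zero_tensors(geom, H)),
                               excitation_cm=10.0)


def _zero_tensors(geom, H):
    n = geom.n_atoms
    return PropertyTensorSet(
        hessian=H,
        dipole_deriv=np.zeros((n, 3, 3)),
        alpha_deriv=np.zeros((n, 3, 3, 3)),
        gprime_deriv=np.zeros((n, 3, 3, 3)),
        a_deriv=np.zeros((n, 3, 3, 3, 3)),
    )


class TestConvolution:
    def test_unit_area_on_fine_grid(self):
        sticks = StickSpectrum(
            frequencies=np.array([5000.0]), raman=np.array([3.7]), roa=np.array([0.01])
        )
        # Lorentzian tails carry ~(2Γ/πL) of the area beyond ±L, so the
        # 1e-3 relative target needs a window of ~±1000 half-widths
        grid = np.arange(0.0, 10000.5, 0.5)
        pair = convolve(sticks, fwhm=10.0, grid=grid)
        area = np.trapezoid(pair.raman, pair.grid)
        assert area == pytest.approx(3.7, rel=1e-3)

    def test_peak_height_of_isolated_stick(self):
        w, fwhm = 2.5, 10.0
        sticks = StickSpectrum(
            frequencies=np.array([900.0]), raman=np.array([w]), roa=np.array([0.0])
        )
        pair = convolve(sticks, fwhm=fwhm, grid=np.arange(500.0, 1300.0, 1.0))
        assert pair.raman.max() == pytest.approx(2.0 * w / (np.pi * fwhm), rel=1e-9)

    def test_coincident_sticks_add_linearly(self):
        one = StickSpectrum(
            frequencies=np.array([700.0, 700.0]),
            raman=np.array([1.0, 2.0]),
            roa=np.array([0.5, -0.2]),
        )
        summed = StickSpectrum(
            frequencies=np.array([700.0]), raman=np.array([3.0]), roa=np.array([0.3])
        )
        grid = np.arange(300.0, 1100.0, 1.0)
        a = convolve(one, grid=grid)
        b = convolve(summed, grid=grid)
        assert np.abs(a.raman - b.raman).max() < 1e-12
        assert np.abs(a.roa - b.roa).max() < 1e-12

    def test_narrow_grid_rejected(self):
        sticks = StickSpectrum(
            frequencies=np.array([1790.0]), raman=np.array([1.0]), roa=np.array([0.0])
        )
        with pytest.raises(ValueError, match="too narrow"):
            convolve(sticks, fwhm=10.0, grid=np.arange(50.0, 1800.0, 1.0))


class TestAveraging:
    def test_single_spectrum_identity(self):
        grid = default_grid()
        pair = SpectrumPair(grid=grid, raman=np.ones_like(grid), roa=np.zeros_like(grid))
        out = average_snapshots([pair])
        assert np.array_equal(out.raman, pair.raman)

    def test_copies_average_to_themselves(self):
        grid = default_grid()
        rng = np.random.default_rng(7)
        pair = SpectrumPair(
            grid=grid, raman=rng.random(len(grid)), roa=rng.standard_normal(len(grid))
        )
        out = average_snapshots([pair] * 5)
        assert np.abs(out.raman - pair.raman).max() < 1e-15

    def test_two_sticks_average_to_half_height(self):
        grid = np.arange(500.0, 1500.0, 1.0)
        s1 = StickSpectrum(np.array([900.0]), np.array([2.0]), np.array([0.0]))
        s2 = StickSpectrum(np.array([1100.0]), np.array([2.0]), np.array([0.0]))
        p1, p2 = convolve(s1, grid=grid), convolve(s2, grid=grid)
        mean = average_snapshots([p1, p2])
        i900 = np.argmin(np.abs(grid - 900.0))
        # half height up to the (tiny) tail of the 1100 band
        assert mean.raman[i900] == pytest.approx(0.5 * p1.raman[i900], rel=2e-3)
        assert np.abs(mean.raman - 0.5 * (p1.raman + p2.raman)).max() < 1e-15

    def test_grid_mismatch_rejected(self):
        p1 = SpectrumPair(np.arange(10.0), np.ones(10), np.zeros(10))
        p2 = SpectrumPair(np.arange(11.0), np.ones(11), np.zeros(11))
        with pytest.raises(ValueError):
            average_snapshots([p1, p2])

    def test_averaging_commutes_with_convolution(self):
        grid = np.arange(300.0, 1500.0, 1.0)
        rng = np.random.default_rng(3)
        sticksets = [
            StickSpectrum(
                frequencies=rng.uniform(500, 1200, 4),
                raman=rng.random(4),
                roa=rng.standard_normal(4) * 1e-3,
            )
            for _ in range(3)
        ]
        mean_of_conv = average_snapshots([convolve(s, grid=grid) for s in sticksets])
        pooled = sticksets[0] + sticksets[1] + sticksets[2]
        pooled_scaled = StickSpectrum(
            pooled.frequencies, pooled.raman / 3.0, pooled.roa / 3.0
        )
        conv_of_pooled = convolve(pooled_scaled, grid=grid)
        assert np.abs(mean_of_conv.raman - conv_of_pooled.raman).max() < 1e-12
        assert np.abs(mean_of_conv.roa - conv_of_pooled.roa).max() < 1e-12


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        grid = default_grid(100.0, 200.0)
        rng = np.random.default_rng(5)
        pair = SpectrumPair(
            grid=grid,
            raman=rng.random(len(grid)),
            roa=1e-3 * rng.standard_normal(len(grid)),
            meta={"temperature": 300.0},
        )
        path = tmp_path / "spec.tsv"
        write_spectrum(pair, path)
        back = read_spectrum(path)
        assert np.abs(back.raman - pair.raman).max() < 1e-9
        assert np.abs(back.roa - pair.roa).max() < 1e-9
        assert back.meta["temperature"] == 300.0
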