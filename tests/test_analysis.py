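"""Baseline correction, water normalization, CID/couplet statistics,
band detection and the collagen-type classifier."""

import numpy as np
import pytest

from collagen_roa.analysis import (
    baseline_correct,
    cid,
    couplet_stats,
    detect_bands,
    normalize_to_water,
    preprocess,
    score_collagen_type,
)
from collagen_roa.spectra import SpectrumPair, default_grid, write_spectrum
from collagen_roa.synthetic import canonical_fixture, make_experiment_spectrum


class TestBaseline:
    def test_pure_polynomial_removed_completely(self):
        grid = default_grid(100.0, 1800.0)
        x = np.linspace(-1, 1, len(grid))
        y = 3.0 + 2.0 * x - 1.5 * x**2 + 0.7 * x**4
        corrected, _, converged = baseline_correct(grid, y, degree=5)
        assert converged
        assert np.abs(corrected).max() < 1e-6 * np.abs(y).max()

    def test_flat_spectrum_unchanged(self):
        grid = default_grid(100.0, 1800.0)
        y = np.full(len(grid), 2.0)
        corrected, _, _ = baseline_correct(grid, y, degree=3)
        assert np.abs(corrected).max() < 1e-8

    def test_band_heights_recovered_under_quartic_baseline(self):
        noise_sd = 0.01
        pair, truth = make_experiment_spectrum(
            bands=[(700.0, 0.8, 0.0), (1100.0, 0.5, 0.0), (1400.0, 0.9, 0.0)],
            baseline_coeffs=(0.5, -0.3, 0.2, 0.1, 0.25),
            noise_sd=noise_sd,
            seed=42,
        )
        corrected, _, _ = baseline_correct(pair.grid, pair.raman, degree=5)
        for center, height, _ in truth["bands"]:
            idx = np.argmin(np.abs(pair.grid - center))
            assert corrected[idx] == pytest.approx(height, abs=3 * noise_sd + 0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(np.arange(4.0), np.arange(4.0), degree=5)


class TestNormalization:
    def _pair_with_water(self, height=5.0):
        grid = default_grid(100.0, 1800.0)
        gamma = 5.0
        raman = height * gamma**2 / ((grid - 1650.0) ** 2 + gamma**2)
        roa = 1e-3 * raman * np.sin(grid / 100.0)
        return SpectrumPair(grid=grid, raman=raman, roa=roa)

    def test_water_peak_scaled_to_one(self):
        pair = self._pair_with_water(5.0)
        out, scale = normalize_to_water(pair)
        assert scale == pytest.approx(5.0, rel=1e-9)
        mask = (out.grid >= 1630.0) & (out.grid <= 1670.0)
        assert out.raman[mask].max() == pytest.approx(1.0, rel=1e-12)

    def test_cid_preserved_pointwise(self):
        pair = self._pair_with_water(3.0)
        out, _ = normalize_to_water(pair)
        strong = pair.raman > 1e-6
        before = pair.roa[strong] / pair.raman[strong]
        after = out.roa[strong] / out.raman[strong]
        assert np.abs(before - after).max() < 1e-12

    def test_zero_spectrum_rejected(self):
        grid = default_grid(100.0, 1800.0)
        pair = SpectrumPair(grid=grid, raman=np.zeros_like(grid), roa=np.zeros_like(grid))
        with pytest.raises(ValueError):
            normalize_to_water(pair)


class TestCID:
    def test_zero_roa_gives_zero_cid(self):
        grid = default_grid(100.0, 1800.0)
        pair = SpectrumPair(grid=grid, raman=np.ones_like(grid), roa=np.zeros_like(grid))
        assert cid(pair, 1000.0) == 0.0

    def test_definition_ir2_il1(self):
        # I_R = 2, I_L = 1  ->  raman 3, roa 1, CID = 1/3
        grid = default_grid(100.0, 1800.0)
        pair = SpectrumPair(
            grid=grid, raman=3.0 * np.ones_like(grid), roa=np.ones_like(grid)
        )
        assert cid(pair, 850.0) == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_collagen_like_pair_cid_below_1e3_at_amide_i_maximum(self):
        pair, _ = canonical_fixture("type_I", seed=0, noise_sd=0.0,
                                    baseline_coeffs=())
        mask = (pair.grid >= 1600.0) & (pair.grid <= 1700.0)
        at = pair.grid[mask][np.argmax(pair.raman[mask])]
        assert abs(cid(pair, at)) < 1.0e-3

    def test_nonpositive_raman_rejected(self):
        grid = default_grid(100.0, 1800.0)
        pair = SpectrumPair(grid=grid, raman=np.zeros_like(grid), roa=np.ones_like(grid))
        with pytest.raises(ValueError):
            cid(pair, 1000.0)

    def test_cid_invariant_under_positive_rescaling(self):
        pair, _ = canonical_fixture("type_I", seed=3, noise_sd=0.0, baseline_coeffs=())
        scaled = SpectrumPair(
            grid=pair.grid, raman=7.3 * pair.raman, roa=7.3 * pair.roa
        )
        for at in (473.0, 1320.0, 1650.0):
            assert cid(pair, at) == pytest.approx(cid(scaled, at), rel=1e-12)


class TestCouplets:
    def _antisymmetric_couplet(self):
        grid = default_grid(1500.0, 1800.0)
        gamma = 5.0
        lor = lambda c: gamma**2 / ((grid - c) ** 2 + gamma**2)
        raman = 1.0 + 0.5 * lor(1660.0) + 0.5 * lor(1630.0)
        roa = 2e-3 * lor(1660.0) - 2e-3 * lor(1630.0)
        return SpectrumPair(grid=grid, raman=raman, roa=roa)

    def test_antisymmetric_couplet_delta_is_twice_lobe_cid(self):
        pair = self._antisymmetric_couplet()
        rep = couplet_stats(pair, (1600.0, 1700.0))
        assert rep.sign_pattern == "(-/+)"
        assert rep.cid1 > 0 > rep.cid2
        assert rep.delta_cid == pytest.approx(2.0 * abs(rep.cid1), rel=1e-6)

    def test_single_signed_region_has_no_couplet(self):
        grid = default_grid(1500.0, 1800.0)
        pair = SpectrumPair(
            grid=grid, raman=np.ones_like(grid), roa=np.abs(np.sin(grid / 40.0)) + 0.01
        )
        with pytest.raises(ValueError, match="no couplet"):
            couplet_stats(pair, (1600.0, 1700.0))

    def test_amide_i_couplet_sign_pattern_of_fixture(self):
        pair, _ = canonical_fixture("type_I", seed=1, noise_sd=0.0, baseline_coeffs=())
        rep = couplet_stats(pair, (1600.0, 1700.0))
        # negative lobe at low, positive at high wavenumber
        assert rep.sign_pattern == "(-/+)"
        assert rep.wavenumber_high > rep.wavenumber_low

    def test_delta_cid_flips_sign_for_enantiomer(self):
        pair, _ = canonical_fixture("type_I", seed=2, noise_sd=0.0, baseline_coeffs=())
        flipped = SpectrumPair(grid=pair.grid, raman=pair.raman, roa=-pair.roa)
        a = couplet_stats(pair, (1600.0, 1700.0)).delta_cid
        b = couplet_stats(flipped, (1600.0, 1700.0)).delta_cid
        assert a == pytest.approx(-b, rel=1e-12)


class TestBandDetection:
    def test_single_lorentzian_located(self):
        grid = default_grid(200.0, 1800.0)
        gamma = 5.0
        y = 0.8 * gamma**2 / ((grid - 473.0) ** 2 + gamma**2)
        bands = detect_bands(grid, y, min_prominence=0.1)
        assert len(bands) == 1
        assert abs(bands[0].center - 473.0) <= 1.0

    def test_nine_wavenumber_doublet_resolution_pinned(self):
        """Two equal bands 9 cm⁻¹ apart at FWHM 10 split into two
        detected peaks pulled toward each other — the pinned behaviour."""
        grid = default_grid(200.0, 1800.0)
        gamma = 5.0
        lor = lambda c: gamma**2 / ((grid - c) ** 2 + gamma**2)
        y = 0.5 * lor(900.0) + 0.5 * lor(909.0)
        bands = detect_bands(grid, y, min_prominence=0.05)
        assert len(bands) == 2
        assert 900.0 <= bands[0].center < bands[1].center <= 909.0

    def test_noise_rarely_yields_bands_at_5_sigma(self):
        grid = default_grid(200.0, 1800.0)
        sigma = 0.01
        clean_runs = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            y = sigma * rng.standard_normal(len(grid))
            if len(detect_bands(grid, y, min_prominence=5.0 * sigma)) == 0:
                clean_runs += 1
        assert clean_runs >= 190  # >= 95% of seeded runs

    def test_signed_detection_reports_negative_bands(self):
        grid = default_grid(200.0, 1800.0)
        gamma = 5.0
        y = -0.4 * gamma**2 / ((grid - 1630.0) ** 2 + gamma**2)
        bands = detect_bands(grid, y, min_prominence=0.1, signed=True)
        assert len(bands) == 1
        assert bands[0].height < 0


class TestClassifier:
    @pytest.mark.parametrize(
        "fixture,expected",
        [
            ("type_I", "type_I"),
            ("type_II", "type_II"),
            ("denatured_I", "denatured_I"),
            ("ambiguous", "indeterminate"),
        ],
    )
    def test_canonical_fixtures_called_correctly(self, fixture, expected):
        pair, _ = canonical_fixture(fixture, seed=0)
        score = score_collagen_type(preprocess(pair))
        assert score.call == expected

    def test_conflicting_evidence_is_indeterminate(self):
        pair, _ = canonical_fixture("ambiguous", seed=5)
        score = score_collagen_type(preprocess(pair))
        assert score.evidence["roa_473_positive"]
        assert score.evidence["raman_306_339_doublet"]
        assert score.call == "indeterminate"

    def test_triple_helix_flag_follows_amide_i_couplet(self):
        pair, _ = canonical_fixture("type_I", seed=0)
        score = score_collagen_type(preprocess(pair))
        assert score.evidence["amide_i_couplet_neg_pos"]

    def test_insufficient_coverage_rejected(self):
        grid = default_grid(600.0, 1800.0)
        pair = SpectrumPair(grid=grid, raman=np.ones_like(grid), roa=np.zeros_like(grid))
        with pytest.raises(ValueError):
            score_collagen_type(pair)


class TestPipelineDeterminism:
    def test_preprocessing_is_byte_deterministic(self, tmp_path):
        paths = []
        for run in range(2):
            pair, _ = canonical_fixture("type_I", seed=9)
            out = preprocess(pair)
            path = tmp_path / f"run{run}.tsv"
            write_spectrum(out, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()
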