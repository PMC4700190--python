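import numpy as np
import pytest

from spiralscan import (
    CalibrationStandard,
    Chromatogram,
    ElutionClass,
    apparent_mass,
    assign_oligomer,
    classify_elution_pattern,
    detect_peaks,
    fit_calibration,
    rechromatography_stability,
)
from spiralscan.sec import Peak, SecError, read_chromatogram_csv, read_standards_csv
from spiralscan.synthetic import (
    TRUTH_V0_ML,
    TRUTH_VT_ML,
    elution_volume_for_mass,
    simulate_chromatogram,
    truth_calibration,
    truth_standards,
)


class TestCalibration:
    def test_exact_line_recovered(self):
        # standards constructed on log10(M) = 6 - 2.3 Kav
        fit = fit_calibration(truth_standards(), TRUTH_V0_ML, TRUTH_VT_ML)
        assert fit.slope == pytest.approx(-2.3, abs=1e-12)
        assert fit.intercept == pytest.approx(6.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_back_prediction_identity(self, standards):
        fit = fit_calibration(standards, TRUTH_V0_ML, TRUTH_VT_ML)
        for s in standards:
            est = apparent_mass(fit, s.elution_ml)
            assert est.mass_kda * 1000 == pytest.approx(s.mass_da, rel=1e-9)

    def test_marker_kit_masses_present(self, standards):
        assert sorted(s.mass_da for s in standards) == [
            29_000, 66_000, 150_000, 200_000, 443_000, 669_000,
        ]

    def test_too_few_standards_or_bad_volumes(self, standards):
        with pytest.raises(SecError):
            fit_calibration(standards[:2], TRUTH_V0_ML, TRUTH_VT_ML)
        with pytest.raises(SecError):
            fit_calibration(standards, 24.0, 8.0)

    def test_apparent_mass_monotone_decreasing(self, standards):
        fit = fit_calibration(standards, TRUTH_V0_ML, TRUTH_VT_ML)
        vols = np.linspace(8.5, 23.0, 40)
        masses = [apparent_mass(fit, v).mass_kda for v in vols]
        assert all(a > b for a, b in zip(masses, masses[1:]))

    def test_void_volume_flagged(self, standards):
        fit = fit_calibration(standards, TRUTH_V0_ML, TRUTH_VT_ML)
        est = apparent_mass(fit, TRUTH_V0_ML)
        assert est.in_void and est.mass_kda is None

    def test_extrapolation_flagged(self, standards):
        fit = fit_calibration(standards, TRUTH_V0_ML, TRUTH_VT_ML)
        beyond = max(s.elution_ml for s in standards) + 2.0
        assert apparent_mass(fit, beyond).extrapolated

    def test_synthetic_14mer_mass_within_1_kda(self, standards):
        fit = fit_calibration(standards, TRUTH_V0_ML, TRUTH_VT_ML)
        est = apparent_mass(fit, elution_volume_for_mass(518.0))
        assert est.mass_kda == pytest.approx(518.0, abs=1.0)


class TestDetectPeaks:
    def test_single_gaussian(self):
        v = np.arange(7.0, 25.0, 0.02)
        y = np.exp(-0.5 * ((v - 12.0) / 0.15) ** 2)
        peaks = detect_peaks(Chromatogram(v, y), v0_ml=8.0)
        assert len(peaks) == 1
        assert abs(peaks[0].apex_volume_ml - 12.0) <= 0.02
        assert peaks[0].area_fraction == pytest.approx(1.0, abs=1e-6)

    def test_two_gaussians_area_fractions(self):
        chrom, truth = simulate_chromatogram(
            [(18, 0.7), (2, 0.3)], noise_sd_au=0.0, seed=0
        )
        peaks = detect_peaks(chrom, v0_ml=TRUTH_V0_ML)
        assert len(peaks) == 2
        fracs = sorted(p.area_fraction for p in peaks)
        assert fracs[0] == pytest.approx(0.3, abs=0.05)
        assert fracs[1] == pytest.approx(0.7, abs=0.05)

    def test_flat_trace_empty(self):
        v = np.arange(7.0, 25.0, 0.02)
        assert detect_peaks(Chromatogram(v, np.ones_like(v))) == []

    def test_too_few_points_rejected(self):
        with pytest.raises(SecError):
            detect_peaks(Chromatogram(np.arange(5.0), np.zeros(5)))

    def test_mass_annotation_from_fit(self, standards):
        fit = fit_calibration(standards, TRUTH_V0_ML, TRUTH_VT_ML)
        chrom, _ = simulate_chromatogram([(14, 1.0)], noise_sd_au=0.0, seed=0)
        (peak,) = detect_peaks(chrom, v0_ml=TRUTH_V0_ML, fit=fit)
        assert peak.apparent_mass_kda == pytest.approx(14 * 37.0, abs=5.0)

    def test_seeded_mixture_recovery(self):
        """Peak count, apex position and area fractions recovered across
        20 random well-separated mixtures."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            species = rng.choice([2, 6, 10, 14, 18], size=rng.integers(1, 4), replace=False)
            weights = rng.dirichlet(np.ones(len(species))) * 0.8 + 0.2 / len(species)
            comp = list(zip(species.tolist(), weights.tolist()))
            chrom, truth = simulate_chromatogram(comp, seed=trial)
            peaks = detect_peaks(chrom, v0_ml=TRUTH_V0_ML)
            assert len(peaks) == len(comp)
            got = sorted((p.apex_volume_ml, p.area_fraction) for p in peaks)
            want = sorted(zip(truth.species_volumes_ml,
                              [w for _, w in truth.composition]))
            for (gv, gf), (wv, wf) in zip(got, want):
                assert abs(gv - wv) <= 0.03  # within ~one grid step
                assert abs(gf - wf) <= 0.05


class TestAssignOligomer:
    @pytest.mark.parametrize("mass,n", [(518, 14), (370, 10), (222, 6), (74, 2)])
    def test_ladder(self, mass, n):
        assert assign_oligomer(mass, 37.0).n == n

    def test_prefer_even_resolves_odd(self):
        assert assign_oligomer(111, 37.0).n in (2, 4)  # 3 -> nearest even
        assert assign_oligomer(111, 37.0, prefer_even=False).n == 3

    def test_scale_invariance(self):
        for mass, mono in [(518, 37.0), (600, 41.0), (90, 37.0)]:
            a = assign_oligomer(mass, mono)
            b = assign_oligomer(3.7 * mass, 3.7 * mono)
            assert a.n == b.n
            assert a.residual == pytest.approx(b.residual)

    def test_positive_masses_required(self):
        with pytest.raises(SecError):
            assign_oligomer(-1.0, 37.0)


class TestClassifyElution:
    REF18 = elution_volume_for_mass(18 * 37.0)
    REF14 = elution_volume_for_mass(14 * 37.0)

    def _classify(self, comp, seed=0):
        chrom, _ = simulate_chromatogram(comp, seed=seed)
        peaks = detect_peaks(chrom, v0_ml=TRUTH_V0_ML)
        return classify_elution_pattern(peaks, self.REF18, self.REF14, TRUTH_V0_ML)

    def test_wild_type_single_18mer_peak(self):
        assert self._classify([(18, 1.0)]) is ElutionClass.MER18

    def test_intermediate_16mer(self):
        assert self._classify([(16, 1.0)]) is ElutionClass.MER16_INTERMEDIATE

    def test_14mer_with_minor_others(self):
        assert self._classify([(14, 0.9), (18, 0.1)]) is ElutionClass.MER14

    def test_multi_peak_with_small_species(self):
        comp = [(14, 0.55), (10, 0.15), (6, 0.10), (2, 0.20)]
        assert self._classify(comp) is ElutionClass.MULTIPLE_SMALLER

    def test_void_dominant_with_shoulder(self):
        assert self._classify([(60, 0.7), (18, 0.3)]) is ElutionClass.EXTENDED_OR_AGGREGATED

    def test_reference_order_enforced(self):
        peak = Peak(10.0, 1.0, 1.0, False)
        with pytest.raises(SecError):
            classify_elution_pattern([peak], self.REF14, self.REF18)

    def test_empty_peaks_rejected(self):
        with pytest.raises(SecError):
            classify_elution_pattern([], self.REF18, self.REF14)


class TestRechromatography:
    def test_rerun_entirely_inside_window(self):
        chrom, _ = simulate_chromatogram([(14, 1.0)], noise_sd_au=0.0, seed=0)
        res = rechromatography_stability([], (9.0, 11.0), chrom)
        assert res.retained_fraction == pytest.approx(1.0, abs=1e-6)
        assert res.verdict == "stable"

    def test_uniform_rerun_gives_window_over_trace_ratio(self):
        v = np.arange(7.0, 25.0 + 1e-9, 0.02)
        chrom = Chromatogram(v, np.ones_like(v))
        res = rechromatography_stability([], (10.0, 14.5), chrom)
        assert res.retained_fraction == pytest.approx(4.5 / 18.0, abs=1e-3)
        assert res.verdict == "redistributed"

    def test_r67c_like_fractions_all_stable(self):
        """Each collected fraction re-runs with most area in its own window."""
        cases = {
            (9.5, 10.5): [(14, 0.8), (10, 0.1), (2, 0.1)],
            (10.6, 13.0): [(10, 0.5), (6, 0.35), (14, 0.1), (2, 0.05)],
            (15.0, 17.0): [(2, 0.85), (6, 0.1), (14, 0.05)],
        }
        for window, comp in cases.items():
            chrom, _ = simulate_chromatogram(comp, seed=13)
            res = rechromatography_stability([], window, chrom)
            assert res.verdict == "stable"
            assert res.retained_fraction >= 0.6

    def test_zero_area_rerun_rejected(self):
        v = np.arange(7.0, 25.0, 0.02)
        with pytest.raises(SecError):
            rechromatography_stability([], (9.0, 11.0), Chromatogram(v, np.zeros_like(v)))


class TestCsvIo:
    def test_chromatogram_csv_round_trip(self, tmp_path):
        chrom, _ = simulate_chromatogram([(18, 1.0)], seed=2)
        p = tmp_path / "trace.csv"
        import pandas as pd

        pd.DataFrame(
            {"volume_ml": chrom.volume_ml, "absorbance_au": chrom.absorbance_au}
        ).to_csv(p, index=False)
        back = read_chromatogram_csv(p)
        np.testing.assert_allclose(back.absorbance_au, chrom.absorbance_au)

    def test_standards_csv(self, tmp_path, standards):
        p = tmp_path / "standards.csv"
        p.write_text(
            "name,mass_da,elution_ml\n"
            + "\n".join(f"{s.name},{s.mass_da},{s.elution_ml}" for s in standards)
        )
        back = read_standards_csv(p)
        assert [s.mass_da for s in back] == [s.mass_da for s in standards]
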