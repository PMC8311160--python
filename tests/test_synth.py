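"""Synthetic-data generator: determinism, decay laws, fixture table."""

import numpy as np
import pytest

from ramanpheno.spectra import ValidationError
from ramanpheno.synth import (
    DEFAULT_WAVENUMBERS as W,
    BandComponent,
    GenotypeProfile,
    OsmoticKinetics,
    StudyDesign,
    balanced_anthocyanin,
    synth_map_series,
    synth_spectrum,
    synth_study,
)


class TestBandComponent:
    def test_invalid_width_and_amplitude_rejected(self):
        with pytest.raises(ValidationError):
            BandComponent(1157.0, 0.0, 1.0, "carotenoid")
        with pytest.raises(ValidationError):
            BandComponent(1157.0, 5.0, -1.0, "carotenoid")

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            BandComponent(1157.0, 5.0, 1.0, "xanthophyll")


class TestSynthSpectrum:
    def test_single_band_peaks_at_its_center(self):
        p = GenotypeProfile(
            name="one-band",
            tissue="green",
            bands=[BandComponent(1157.0, 6.0, 2.0, "carotenoid")],
            degradation={"control": 0.0},
            amplitude_cv=0.0,
            gain_cv=0.0,
            additive_noise_frac=0.0,
            background_poly=(0.0,),
            fluorescence=(0.0, 1250.0, 300.0),
        )
        s = synth_spectrum(p, seed=0)
        assert W[np.argmax(s.intensities)] == 1157.0
        assert s.intensities.max() == pytest.approx(2.0, rel=1e-12)

    def test_1524_band_strongest_in_green_default(self, green):
        s = synth_spectrum(green.noiseless(), seed=0)
        bands = s.intensities - green.background(W)
        a = {c: bands[np.abs(W - c) <= 3].max() for c in (1007.0, 1157.0, 1524.0)}
        assert a[1524.0] > a[1157.0] > a[1007.0]

    def test_white_has_lower_carotenoid_amplitude_than_green(self, green, white):
        sg = synth_spectrum(green.noiseless(), seed=1)
        sw = synth_spectrum(white.noiseless(), seed=1)
        g = (sg.intensities - green.background(W))[np.abs(W - 1157) <= 3].max()
        w_ = (sw.intensities - white.background(W))[np.abs(W - 1157) <= 3].max()
        assert w_ < g

    def test_negative_scale_rejected(self, green):
        with pytest.raises(ValidationError, match="scale"):
            synth_spectrum(green, scale=-1.0)

    def test_same_seed_bit_identical(self, green):
        a = synth_spectrum(green, seed=9)
        b = synth_spectrum(green, seed=9)
        assert np.array_equal(a.intensities, b.intensities)
        c = synth_spectrum(green, seed=10)
        assert not np.array_equal(a.intensities, c.intensities)


class TestStudyGenerator:
    def test_design_counts(self, profiles):
        design = StudyDesign(genotypes=("B73",))
        assert design.n_spectra_per_genotype == 2880  # 2 x 3 x 5 x 8 x 12
        small = StudyDesign(
            genotypes=("B73",), replicates=1, plants=1, spectra_per_day=2,
            days=(0, 1),
        )
        ds = synth_study(profiles, small, seed=0)
        assert ds.n_spectra == 2 * 1 * 1 * 2 * 2

    def test_days_must_start_at_zero(self):
        with pytest.raises(ValidationError):
            StudyDesign(genotypes=("B73",), days=(1, 2, 3))

    def test_zero_degradation_zero_noise_is_time_invariant(self, profiles):
        p = profiles["B73"].noiseless()
        ds = synth_study(
            {"B73": p},
            StudyDesign(genotypes=("B73",), treatments=("control",),
                        replicates=1, plants=1, spectra_per_day=1),
            seed=0,
        )
        days = sorted(ds.records)
        y0 = ds.records[days[0]][0].intensities
        for k in days[1:]:
            np.testing.assert_allclose(ds.records[k][0].intensities, y0, atol=1e-12)

    def test_linear_decay_hits_exact_day7_ratio(self):
        # r = 0.22, zero noise, single carotenoid band -> day-7 / day-0
        # amplitude ratio exactly 0.78
        p = GenotypeProfile(
            name="pure-car",
            tissue="green",
            bands=[BandComponent(1157.0, 6.0, 1.0, "carotenoid")],
            degradation={"drought": 0.22},
            amplitude_cv=0.0, gain_cv=0.0, additive_noise_frac=0.0,
            background_poly=(0.0,), fluorescence=(0.0, 1250.0, 300.0),
        )
        ds = synth_study(
            {"pure-car": p},
            StudyDesign(genotypes=("pure-car",), treatments=("drought",),
                        replicates=1, plants=1, spectra_per_day=1),
            seed=0,
        )
        def amp(day):
            return ds.records[("pure-car", "drought", 1, 1, day)][0].intensities.max()
        assert amp(7) / amp(0) == pytest.approx(0.78, abs=1e-12)
        # intermediate days follow A0 * (1 - r d / 7) exactly
        for d in range(8):
            assert amp(d) == pytest.approx(1.0 - 0.22 * d / 7, abs=1e-12)

    def test_generator_expectation_matches_decay_law(self, profiles):
        # noiseless band amplitude follows A0 * (1 - r d / 7) to 1e-12
        p = profiles["OH28"].noiseless()
        r = p.degradation["drought"]
        ds = synth_study(
            {"OH28": p},
            StudyDesign(genotypes=("OH28",), treatments=("drought",),
                        replicates=1, plants=1, spectra_per_day=1),
            seed=0,
        )
        bg = p.background(W)
        i1157 = np.argmin(np.abs(W - 1157.0))
        a0 = ds.records[("OH28", "drought", 1, 1, 0)][0].intensities[i1157] - bg[i1157]
        for d in range(8):
            ad = ds.records[("OH28", "drought", 1, 1, d)][0].intensities[i1157] - bg[i1157]
            # subtract the (tiny, anthocyanin-tail) cross contribution by
            # comparing against the exact generator law at the same pixel
            expected = p.band_sum(
                W, carotenoid_scale=1 - r * d / 7,
                anthocyanin_amplitude=balanced_anthocyanin(p, 1 - r * d / 7, W),
            )[i1157]
            assert ad == pytest.approx(expected, abs=1e-12)

    def test_band_energy_is_conserved_across_days(self, profiles):
        p = profiles["CML176"].noiseless()
        e = []
        for s in (1.0, 0.9, 0.78):
            b = balanced_anthocyanin(p, s, W)
            y = p.band_sum(W, carotenoid_scale=s, anthocyanin_amplitude=b)
            e.append(y @ y)
        np.testing.assert_allclose(e, e[0], rtol=1e-12)

    def test_same_seed_reproducible(self, profiles):
        design = StudyDesign(genotypes=("B73",), replicates=1, plants=2,
                             spectra_per_day=3, days=(0, 1))
        a = synth_study(profiles, design, seed=4)
        b = synth_study(profiles, design, seed=4)
        for key in a.records:
            for sa, sb in zip(a.records[key], b.records[key]):
                assert np.array_equal(sa.intensities, sb.intensities)

    def test_missing_profile_rejected(self, profiles):
        with pytest.raises(ValidationError, match="profile"):
            synth_study({"B73": profiles["B73"]},
                        StudyDesign(genotypes=("B73", "Mo17")), seed=0)


class TestKinetics:
    def test_half_life_table_must_decrease(self):
        with pytest.raises(ValidationError, match="decreasing"):
            OsmoticKinetics(half_life_min={100.0: 5.0, 250.0: 7.0})

    def test_floor_range(self):
        with pytest.raises(ValidationError):
            OsmoticKinetics(half_life_min={100.0: 10.0, 250.0: 5.0}, floor=1.0)

    def test_half_life_definition(self):
        k = OsmoticKinetics(half_life_min={100.0: 5.0}, floor=0.0)
        assert k.decay_fraction(100.0, 5.0) == pytest.approx(0.5, abs=1e-15)
        assert k.decay_fraction(100.0, 0.0) == pytest.approx(1.0, abs=1e-15)
        assert k.decay_fraction(0.0, 45.0) == 1.0

    def test_unknown_concentration_rejected(self, kinetics):
        with pytest.raises(ValidationError, match="concentration"):
            kinetics.half_life(75.0)

    def test_higher_concentration_decays_faster(self, kinetics):
        for t in (5.0, 15.0, 30.0):
            fr = [kinetics.decay_fraction(c, t) for c in (100.0, 150.0, 250.0)]
            assert fr[0] > fr[1] > fr[2]


class TestMapSeries:
    def test_xy_grid_has_80_points(self, kinetics):
        maps = synth_map_series(kinetics, 250, "XY80", seed=1)
        assert all(m.n_points == 80 for m in maps)
        assert maps[0].is_pre and maps[0].timepoint_min is None
        assert [m.timepoint_min for m in maps[1:]] == [0, 5, 15, 30, 45]

    def test_xz_grid_has_30_points(self, kinetics):
        maps = synth_map_series(kinetics, 100, "XZ30", seed=1)
        assert all(m.n_points == 30 for m in maps)
        assert maps[0].axes == "XZ"

    def test_water_control_mean_stays_at_pre_level(self, kinetics, band_1157):
        from ramanpheno.mapping import band_intensity_map

        maps = synth_map_series(kinetics, 0, "XY80", seed=5)
        means = [np.mean(band_intensity_map(m, band_1157).values) for m in maps]
        np.testing.assert_allclose(means, means[0], rtol=0.02)

    def test_unknown_concentration_rejected(self, kinetics):
        with pytest.raises(ValidationError, match="concentration"):
            synth_map_series(kinetics, 75, "XY80", seed=1)

    def test_unknown_grid_rejected(self, kinetics):
        with pytest.raises(ValidationError, match="grid"):
            synth_map_series(kinetics, 100, "XY81", seed=1)

    def test_white_tissue_does_not_decay(self, kinetics, white, band_1157):
        from ramanpheno.mapping import band_intensity_map

        maps = synth_map_series(kinetics, 250, "XY80", seed=1, profile=white)
        means = [np.mean(band_intensity_map(m, band_1157).values) for m in maps]
        np.testing.assert_allclose(means, means[0], rtol=0.02)

    def test_same_seed_bit_identical(self, kinetics):
        a = synth_map_series(kinetics, 150, "XY80", seed=8)
        b = synth_map_series(kinetics, 150, "XY80", seed=8)
        for ma, mb in zip(a, b):
            for sa, sb in zip(ma.spectra, mb.spectra):
                assert np.array_equal(sa.intensities, sb.intensities)


class TestDefaultProfiles:
    def test_six_profiles_with_reported_rates(self, profiles):
        assert len(profiles) == 6
        expected = {"CML176": 0.22, "OH28": 0.20, "B73": 0.06,
                    "lox2": 0.10, "lox4": 0.03, "B73-dark": 0.0}
        for name, r in expected.items():
            assert profiles[name].degradation["drought"] == pytest.approx(r)

    def test_controls_do_not_degrade(self, profiles):
        for p in profiles.values():
            assert p.degradation["control"] == 0.0

    def test_nils_share_b73_initial_amplitudes(self, profiles):
        for center in (1007.0, 1157.0, 1524.0):
            a = {g: profiles[g].band_amplitude(center) for g in ("B73", "lox2", "lox4")}
            assert a["B73"] == a["lox2"] == a["lox4"]

    def test_inbreds_have_distinct_initial_amplitudes(self, profiles):
        amps = {g: profiles[g].band_amplitude(1157.0) for g in ("B73", "CML176", "OH28")}
        assert len(set(amps.values())) == 3

    def test_white_tissue_strictly_below_green(self, profiles):
        for center in (1007.0, 1157.0, 1524.0):
            assert (
                profiles["B73-dark"].band_amplitude(center)
                < profiles["B73"].band_amplitude(center)
            )
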