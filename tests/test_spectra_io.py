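"""Container invariants and CSV/manifest round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramanpheno.io import (
    dataset_from_spectra,
    read_manifest,
    read_spectra,
    write_manifest,
    write_spectra,
)
from ramanpheno.spectra import (
    FormatError,
    SampleMeta,
    Spectrum,
    SpectrumMap,
    StudyDataset,
    ValidationError,
)
from ramanpheno.synth import default_kinetics, synth_map_series


def make_spectrum(n=5, **meta):
    w = np.arange(1000.0, 1000.0 + n)
    return Spectrum(w, np.linspace(1.0, 2.0, n), SampleMeta(sample_id="s", **meta))


class TestSpectrumInvariants:
    def test_basic_parse(self):
        s = Spectrum([1000, 1001, 1002], [1.0, 2.0, 3.0])
        assert np.array_equal(s.intensities, [1, 2, 3])

    @pytest.mark.parametrize(
        "wavenumbers,intensities",
        [
            ([1000, 999, 1001], [1, 2, 3]),       # non-monotonic
            ([1000, 1000, 1001], [1, 2, 3]),      # repeated grid point
            ([1000, 1001], [1, 2, 3]),            # length mismatch
            ([], []),                              # empty
            ([1000, 1001, 1002], [1, np.nan, 3]), # non-finite
        ],
    )
    def test_invalid_spectra_rejected(self, wavenumbers, intensities):
        with pytest.raises(ValidationError):
            Spectrum(np.asarray(wavenumbers, float), np.asarray(intensities, float))

    def test_unknown_treatment_rejected(self):
        with pytest.raises(ValidationError):
            make_spectrum(treatment="flood")

    @pytest.mark.parametrize("label", ["control", "drought", "mannitol:150"])
    def test_known_treatments_accepted(self, label):
        make_spectrum(treatment=label)

    @given(
        start=st.floats(min_value=100, max_value=3000),
        steps=st.lists(st.floats(min_value=1e-3, max_value=10), min_size=2, max_size=30),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_any_strictly_increasing_grid_is_accepted(self, start, steps):
        w = start + np.cumsum(steps)
        Spectrum(w, np.zeros(len(w)))

    def test_reversed_grid_names_offending_index(self):
        with pytest.raises(ValidationError, match="index 2"):
            Spectrum([1000.0, 1001.0, 1000.5], [1.0, 2.0, 3.0])


class TestMapAndStudyInvariants:
    def test_duplicate_positions_rejected(self):
        s = make_spectrum()
        with pytest.raises(ValidationError, match="unique"):
            SpectrumMap("XY", [[0, 0], [0, 0]], [s, make_spectrum()])

    def test_mixed_grids_rejected(self):
        with pytest.raises(ValidationError, match="grid"):
            SpectrumMap("XY", [[0, 0], [1, 0]], [make_spectrum(5), make_spectrum(6)])

    def test_empty_map_rejected(self):
        with pytest.raises(ValidationError):
            SpectrumMap("XY", np.empty((0, 2)), [])

    def test_bad_axes_rejected(self):
        with pytest.raises(ValidationError):
            SpectrumMap("YZ", [[0.0, 0.0]], [make_spectrum()])

    def test_days_must_be_contiguous_from_zero(self):
        good = {("g", "control", 1, 1, d): [make_spectrum()] for d in (0, 1, 2)}
        StudyDataset(dict(good))
        bad = {("g", "control", 1, 1, d): [make_spectrum()] for d in (1, 2)}
        with pytest.raises(ValidationError, match="contiguous"):
            StudyDataset(bad)
        gappy = {("g", "control", 1, 1, d): [make_spectrum()] for d in (0, 2)}
        with pytest.raises(ValidationError, match="contiguous"):
            StudyDataset(gappy)


class TestCsvRoundTrip:
    def test_three_point_csv(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "sample_id,wavenumber_cm1,intensity\n"
            "a,1000,1\na,1001,2\na,1002,3\n"
        )
        (s,) = read_spectra(p, "csv")
        assert np.array_equal(s.wavenumbers, [1000, 1001, 1002])
        assert np.array_equal(s.intensities, [1, 2, 3])

    def test_non_monotonic_column_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "sample_id,wavenumber_cm1,intensity\n"
            "a,1000,1\na,1002,2\na,1001,3\n"
        )
        with pytest.raises(FormatError, match="row 4"):
            read_spectra(p, "csv")

    def test_empty_list_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        write_spectra([], p, "csv")
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1
        assert "wavenumber_cm1" in lines[0]
        assert read_spectra(p, "csv") == []

    @given(
        n=st.integers(min_value=2, max_value=8),
        day=st.integers(min_value=0, max_value=7),
        rep=st.integers(min_value=1, max_value=3),
        treatment=st.sampled_from(["control", "drought"]),
        scale=st.floats(min_value=1e-3, max_value=1e6),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_round_trip_identity(self, tmp_path_factory, n, day, rep, treatment, scale):
        rng = np.random.default_rng(n * 100 + day)
        w = np.sort(rng.uniform(400, 1800, size=n))
        w = w + np.arange(n) * 1e-3  # enforce strict increase
        s = Spectrum(
            w,
            scale * rng.normal(size=n),
            SampleMeta(
                sample_id="x1",
                genotype="B73",
                treatment=treatment,
                replicate=rep,
                plant=2,
                day=day,
                tissue="green",
            ),
        )
        p = tmp_path_factory.mktemp("rt") / "s.csv"
        write_spectra([s], p, "csv")
        (back,) = read_spectra(p, "csv")
        np.testing.assert_allclose(back.wavenumbers, s.wavenumbers, rtol=1e-9)
        np.testing.assert_allclose(back.intensities, s.intensities, rtol=1e-9)
        assert back.meta.genotype == "B73"
        assert back.meta.treatment == treatment
        assert back.meta.replicate == rep
        assert back.meta.day == day
        assert back.meta.tissue == "green"

    def test_metadata_columns_present(self, tmp_path):
        s = make_spectrum(genotype="OH28", treatment="drought", tissue="green")
        p = tmp_path / "meta.csv"
        write_spectra([s], p, "csv")
        header = p.read_text().splitlines()[0].split(",")
        for col in ("genotype", "treatment", "replicate", "plant", "day_or_min", "tissue"):
            assert col in header


class TestMapCsv:
    def test_map_round_trip_80_points(self, tmp_path):
        series = synth_map_series(default_kinetics(), 150, "XY80", seed=3)
        m = series[0]
        p = tmp_path / "map.csv"
        write_spectra(m, p, "map_csv")
        back = read_spectra(p, "map_csv")
        assert isinstance(back, SpectrumMap)
        assert back.n_points == 80
        assert back.axes == "XY"
        assert back.is_pre == m.is_pre
        assert back.meta["mannitol_mm"] == 150.0
        np.testing.assert_allclose(back.positions, m.positions, rtol=1e-9)
        for a, b in zip(back.spectra, m.spectra):
            np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-9)

    def test_xz_axis_round_trips(self, tmp_path):
        m = synth_map_series(default_kinetics(), 100, "XZ30", seed=3)[1]
        p = tmp_path / "xz.csv"
        write_spectra(m, p, "map_csv")
        assert '"axes": "XZ"' in p.read_text().splitlines()[0]
        back = read_spectra(p, "map_csv")
        assert back.axes == "XZ"
        assert back.n_points == 30


class TestManifest:
    def test_manifest_round_trip(self, tmp_path):
        spectra = [make_spectrum(genotype="B73", treatment="control",
                                 replicate=1, plant=1, day=0)]
        write_spectra(spectra, tmp_path / "a.csv", "csv")
        write_manifest(tmp_path / "manifest.json",
                       [{"path": "a.csv", "format": "csv"}],
                       design={"genotypes": ["B73"]})
        objects, design = read_manifest(tmp_path / "manifest.json")
        assert design == {"genotypes": ["B73"]}
        assert len(objects) == 1 and len(objects[0]) == 1

    def test_dataset_from_spectra_requires_complete_keys(self):
        with pytest.raises(ValidationError, match="complete"):
            dataset_from_spectra([make_spectrum(genotype="B73")])
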