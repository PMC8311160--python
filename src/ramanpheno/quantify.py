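"""Band quantification on preprocessed spectra.

Band amplitude is the maximum intensity inside a +/- half-window around the
nominal band center — robust to small center jitter, matching the "peak
height" readout used for carotenoid quantification.  The 1157 cm^-1
carotenoid band is the default quantification band; the intrinsically
stronger 1524 cm^-1 band is computed but excluded from degradation
statistics because the anthocyanin band overlaps it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

from .spectra import Spectrum, ValidationError

__all__ = [
    "BandDefinition",
    "band_amplitude",
    "band_peak_position",
    "strongest_band",
    "mean_spectrum",
    "default_bands",
    "default_band",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named quantification window: center +/- half_window, in cm^-1."""

    name: str
    center: float
    half_window: float = 10.0

    def __post_init__(self) -> None:
        if self.half_window <= 0:
            raise ValidationError("band half-window must be > 0")


def _band_slice(w: np.ndarray, band: BandDefinition) -> slice:
    if band.center < w[0] or band.center > w[-1]:
        raise ValidationError(
            f"band {band.name!r} center {band.center} cm-1 lies outside the "
            f"grid [{w[0]:g}, {w[-1]:g}]"
        )
    lo = np.searchsorted(w, band.center - band.half_window, side="left")
    hi = np.searchsorted(w, band.center + band.half_window, side="right")
    if hi <= lo:
        raise ValidationError(
            f"band window {band.name!r} contains no grid points"
        )
    return slice(int(lo), int(hi))


def band_amplitude(spectrum: Spectrum, band: BandDefinition) -> float:
    """Maximum intensity within the band window (normalized units)."""
    sl = _band_slice(spectrum.wavenumbers, band)
    return float(spectrum.intensities[sl].max())


def band_peak_position(spectrum: Spectrum, band: BandDefinition) -> float:
    """Wavenumber of the windowed intensity maximum (cm^-1)."""
    sl = _band_slice(spectrum.wavenumbers, band)
    i = int(np.argmax(spectrum.intensities[sl]))
    return float(spectrum.wavenumbers[sl][i])


def strongest_band(
    spectrum: Spectrum, candidates: list[BandDefinition]
) -> BandDefinition:
    """Candidate with the largest band amplitude; ties go to the lowest center."""
    if not candidates:
        raise ValidationError("strongest_band needs at least one candidate")
    amps = [(band_amplitude(spectrum, b), -b.center, b) for b in candidates]
    # max amplitude wins; among exact ties the lower center wavenumber wins
    best = max(amps, key=lambda t: (t[0], t[1]))
    return best[2]


def mean_spectrum(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of spectra sharing one wavenumber grid."""
    if not spectra:
        raise ValidationError("cannot average an empty list of spectra")
    w0 = spectra[0].wavenumbers
    for k, s in enumerate(spectra[1:], start=1):
        if len(s.wavenumbers) != len(w0) or not np.allclose(
            s.wavenumbers, w0, rtol=1e-9, atol=1e-9
        ):
            raise ValidationError(f"spectrum {k} is not on the shared grid")
    mean = np.mean([s.intensities for s in spectra], axis=0)
    return spectra[0].with_intensities(mean, mean_of_n=len(spectra))


def default_bands() -> dict[str, BandDefinition]:
    """Packaged carotenoid band table (1007 / 1157 / 1524 cm^-1)."""
    text = importlib.resources.files("ramanpheno").joinpath(
        "data", "bands.yaml"
    ).read_text()
    doc = yaml.safe_load(text)
    return {
        name: BandDefinition(name, float(b["center"]), float(b["half_window"]))
        for name, b in doc["bands"].items()
    }


def default_band() -> BandDefinition:
    """The default quantification band (carotenoid 1157 cm^-1)."""
    text = importlib.resources.files("ramanpheno").joinpath(
        "data", "bands.yaml"
    ).read_text()
    doc = yaml.safe_load(text)
    return default_bands()[doc["default"]]
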