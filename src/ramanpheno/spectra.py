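"""Core containers for Raman spectra, spatial spectrum maps and study datasets.

A :class:`Spectrum` is a single wavenumber-indexed intensity trace with sample
metadata.  A :class:`SpectrumMap` is a spatial grid of spectra with micron
coordinates (XY surface maps or XZ depth maps).  A :class:`StudyDataset`
collects spectra over the full longitudinal drought-study design
(genotype x treatment x replicate x plant x day).

Intensities are detector counts in arbitrary units; wavenumbers are Raman
shifts in cm^-1 and must be strictly increasing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "FormatError",
    "SampleMeta",
    "Spectrum",
    "SpectrumMap",
    "StudyDataset",
]


class ValidationError(ValueError):
    """An object violates a domain invariant (bad metadata, bad shapes...)."""


class FormatError(ValueError):
    """A file does not conform to the documented on-disk format."""


# control / drought for the in-vivo study; "mannitol:<mM>" for the in-situ
# osmotic-stress map series ("mannitol:0" is the deionized-water control).
_TREATMENT_RE = re.compile(r"^(control|drought|mannitol:\d+(\.\d+)?)$")
_TISSUES = ("green", "white")


def validate_treatment(label: str | None) -> None:
    if label is None:
        return
    if not _TREATMENT_RE.match(label):
        raise ValidationError(
            f"unknown treatment label {label!r}; expected 'control', 'drought' "
            "or 'mannitol:<mM>'"
        )


@dataclass
class SampleMeta:
    """Metadata attached to a single spectrum.

    ``day`` indexes the longitudinal in-vivo study (integer >= 0);
    ``minute`` is the mannitol map-series timepoint.  ``extras`` carries
    free-form provenance (e.g. preprocessing parameters).
    """

    sample_id: str = ""
    genotype: str | None = None
    treatment: str | None = None
    replicate: int | None = None
    plant: int | None = None
    day: int | None = None
    minute: float | None = None
    tissue: str | None = None
    leaf: int | None = None
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        validate_treatment(self.treatment)
        if self.tissue is not None and self.tissue not in _TISSUES:
            raise ValidationError(f"unknown tissue {self.tissue!r}")
        if self.day is not None and self.day < 0:
            raise ValidationError("day must be >= 0")


@dataclass
class Spectrum:
    """One Raman trace: intensity vs wavenumber plus sample metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError("wavenumbers and intensities must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise ValidationError(
                f"length mismatch: {len(self.wavenumbers)} wavenumbers vs "
                f"{len(self.intensities)} intensities"
            )
        if len(self.wavenumbers) == 0:
            raise ValidationError("empty spectrum")
        d = np.diff(self.wavenumbers)
        if len(d) and not np.all(d > 0):
            i = int(np.argmin(d > 0))
            raise ValidationError(
                f"wavenumbers not strictly increasing at index {i + 1} "
                f"(value {self.wavenumbers[i + 1]:g} after {self.wavenumbers[i]:g})"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities contain non-finite values")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValidationError("wavenumbers contain non-finite values")
        self.meta.validate()

    # -- helpers -----------------------------------------------------------

    def with_intensities(self, intensities: np.ndarray, **extra_meta) -> "Spectrum":
        """Copy of this spectrum with new intensities (grid and meta shared)."""
        meta = replace(self.meta, extras=dict(self.meta.extras, **extra_meta))
        return Spectrum(self.wavenumbers, np.asarray(intensities, float), meta)

    @property
    def uniform_step(self) -> float | None:
        """Grid step if the wavenumber grid is uniform, else ``None``."""
        d = np.diff(self.wavenumbers)
        if len(d) == 0:
            return None
        step = float(d[0])
        if np.allclose(d, step, rtol=1e-8, atol=1e-10 * max(abs(step), 1.0)):
            return step
        return None

    def __eq__(self, other) -> bool:  # numeric equality, used by round-trip tests
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.intensities, other.intensities)
            and self.meta == other.meta
        )


@dataclass
class SpectrumMap:
    """Spatial grid of spectra with micron coordinates.

    ``axes`` is ``"XY"`` (surface map) or ``"XZ"`` (depth map); ``positions``
    is an ``(n, 2)`` array of micron coordinates in the axis order given by
    ``axes``.  All member spectra must share one wavenumber grid.  ``meta``
    carries acquisition settings: laser spot size (um), power (mW),
    integration time (s), mannitol concentration (mM), timepoint (min) and
    whether the map was taken pre-treatment.
    """

    axes: str
    positions: np.ndarray
    spectra: list[Spectrum]
    grid_shape: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.axes not in ("XY", "XZ"):
            raise ValidationError(f"axes must be 'XY' or 'XZ', got {self.axes!r}")
        if len(self.spectra) == 0:
            raise ValidationError("a map must contain at least one spectrum")
        if self.positions.shape != (len(self.spectra), 2):
            raise ValidationError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.spectra)} spectra"
            )
        seen = {tuple(np.round(p, 6)) for p in self.positions}
        if len(seen) != len(self.spectra):
            raise ValidationError("map positions are not unique")
        w0 = self.spectra[0].wavenumbers
        for k, s in enumerate(self.spectra[1:], start=1):
            if len(s.wavenumbers) != len(w0) or not np.allclose(
                s.wavenumbers, w0, rtol=1e-9, atol=1e-9
            ):
                raise ValidationError(
                    f"spectrum {k} is not on the shared wavenumber grid"
                )
        if self.grid_shape is not None:
            nx, ny = self.grid_shape
            if nx * ny != len(self.spectra):
                raise ValidationError(
                    f"grid_shape {self.grid_shape} inconsistent with "
                    f"{len(self.spectra)} points"
                )

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    @property
    def n_points(self) -> int:
        return len(self.spectra)

    @property
    def is_pre(self) -> bool:
        return bool(self.meta.get("is_pre", False))

    @property
    def timepoint_min(self) -> float | None:
        return self.meta.get("timepoint_min")

    def intensity_matrix(self) -> np.ndarray:
        """Stack member intensities into an ``(n_points, n_wavenumbers)`` array."""
        return np.vstack([s.intensities for s in self.spectra])


StudyKey = tuple[str, str, int, int, int]  # genotype, treatment, replicate, plant, day


@dataclass
class StudyDataset:
    """Longitudinal collection of spectra keyed by the study design.

    ``records`` maps ``(genotype, treatment, replicate, plant, day)`` to the
    list of spectra acquired from that plant on that day (twelve per day in
    the default design).  Days within the dataset must form a contiguous
    ``0..D`` range.
    """

    records: dict[StudyKey, list[Spectrum]]
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.records:
            raise ValidationError("empty study dataset")
        days = sorted({k[4] for k in self.records})
        if days[0] != 0 or days != list(range(days[-1] + 1)):
            raise ValidationError(
                f"days must form a contiguous 0..D range, got {days}"
            )
        for key, spectra in self.records.items():
            if len(key) != 5:
                raise ValidationError(f"incomplete key tuple {key!r}")
            if not spectra:
                raise ValidationError(f"no spectra for key {key!r}")
            validate_treatment(key[1])

    @property
    def days(self) -> list[int]:
        return sorted({k[4] for k in self.records})

    @property
    def genotypes(self) -> list[str]:
        return sorted({k[0] for k in self.records})

    @property
    def treatments(self) -> list[str]:
        return sorted({k[1] for k in self.records})

    @property
    def n_spectra(self) -> int:
        return sum(len(v) for v in self.records.values())

    def iter_spectra(self) -> Iterator[tuple[StudyKey, Spectrum]]:
        for key in sorted(self.records):
            for s in self.records[key]:
                yield key, s

    def subset(self, genotypes: Sequence[str] | None = None,
               treatments: Sequence[str] | None = None) -> "StudyDataset":
        recs = {
            k: v
            for k, v in self.records.items()
            if (genotypes is None or k[0] in genotypes)
            and (treatments is None or k[1] in treatments)
        }
        if not recs:
            raise ValidationError("subset selects no records")
        return StudyDataset(recs, dict(self.design))
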