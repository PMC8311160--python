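"""Synthetic leaf Raman spectra with the statistical structure the analysis assumes.

The generator emulates 532 nm leaf spectra: a broad autofluorescence
background (cubic polynomial plus one broad Gaussian), Lorentzian Raman
bands — the carotenoid triplet at 1007 / 1157 / 1524 cm^-1, chlorophyll
bands in green tissue, and an anthocyanin band at 1530 cm^-1 that overlaps
the 1524 cm^-1 carotenoid band — and Gaussian detector noise.

Two stress designs are generated:

* **In-vivo drought study** (:func:`synth_study`): the expected carotenoid
  band amplitude declines linearly from A0 at day 0 to A0*(1-r) at day 7 in
  stressed groups, where r is the genotype's drought degradation fraction;
  controls do not decline.  As carotenoids degrade, the anthocyanin band
  grows so that total Raman band energy is conserved (anthocyanin
  accumulation is a known companion response to osmotic stress); this keeps
  the unit-vector-normalized 1157 cm^-1 amplitude proportional to true
  carotenoid content.
* **In-situ mannitol map series** (:func:`synth_map_series`): per-pixel
  expected carotenoid amplitude decays exponentially in minutes,
  ``A(t) = A0*(floor + (1-floor)*2^(-t/half_life(conc)))``, with half-life
  decreasing in mannitol concentration.  White (dark-grown, chlorophyll-less)
  tissue does not decay.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .spectra import SampleMeta, Spectrum, SpectrumMap, StudyDataset, ValidationError

__all__ = [
    "BandComponent",
    "GenotypeProfile",
    "OsmoticKinetics",
    "StudyDesign",
    "DEFAULT_WAVENUMBERS",
    "MAP_GRIDS",
    "lorentzian",
    "synth_spectrum",
    "synth_study",
    "synth_map_series",
    "carotenoid_series",
    "default_profiles",
    "default_kinetics",
    "load_profiles",
    "load_kinetics",
]

#: Default wavenumber grid: 400-1800 cm^-1 at 1 cm^-1 steps, spanning every
#: band the analysis discusses at adequate resolution.
DEFAULT_WAVENUMBERS = np.arange(400.0, 1800.0 + 0.5, 1.0)

#: Map geometries: XY surface maps are 180 x 140 um with 80 sampling points
#: (10 x 8); XZ depth maps are 160 x 15 um with 30 points (10 x 3).
MAP_GRIDS = {
    "XY80": {"axes": "XY", "shape": (10, 8), "extent_um": (180.0, 140.0)},
    "XZ30": {"axes": "XZ", "shape": (10, 3), "extent_um": (160.0, 15.0)},
}

_BAND_LABELS = ("carotenoid", "chlorophyll", "anthocyanin", "other")


def lorentzian(w: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-peak Lorentzian line shape."""
    return hwhm**2 / ((w - center) ** 2 + hwhm**2)


@dataclass
class BandComponent:
    """One Raman band: Lorentzian center, half-width at half-maximum, amplitude."""

    center: float
    hwhm: float
    amplitude: float
    label: str = "other"

    def __post_init__(self) -> None:
        if self.hwhm <= 0:
            raise ValidationError("band width must be > 0")
        if self.amplitude < 0:
            raise ValidationError("band amplitude must be >= 0")
        if self.label not in _BAND_LABELS:
            raise ValidationError(f"unknown band label {self.label!r}")

    def profile(self, w: np.ndarray) -> np.ndarray:
        return self.amplitude * lorentzian(w, self.center, self.hwhm)


@dataclass
class GenotypeProfile:
    """Generative parameters for one genotype/tissue fixture.

    ``degradation`` maps treatment -> day-0 to day-7 relative carotenoid loss
    (0 for controls).  ``amplitude_cv`` is per-spectrum lognormal variation
    of carotenoid content; ``gain_cv`` is per-spectrum overall intensity
    drift (what unit-vector normalization removes); ``additive_noise_frac``
    is the detector-noise SD as a fraction of the maximum band height.
    """

    name: str
    tissue: str
    bands: list[BandComponent]
    degradation: dict[str, float]
    amplitude_cv: float = 0.05
    gain_cv: float = 0.05
    additive_noise_frac: float = 0.01
    background_poly: tuple[float, ...] = (3.0, 0.8, -0.5, 0.3)
    fluorescence: tuple[float, float, float] = (5.0, 1250.0, 300.0)  # height, center, sigma

    def __post_init__(self) -> None:
        if self.tissue not in ("green", "white"):
            raise ValidationError(f"unknown tissue {self.tissue!r}")
        for t, r in self.degradation.items():
            if not 0.0 <= r <= 1.0:
                raise ValidationError(
                    f"degradation fraction for {t!r} must be in [0, 1], got {r}"
                )
        for v in (self.amplitude_cv, self.gain_cv, self.additive_noise_frac):
            if v < 0:
                raise ValidationError("noise parameters must be >= 0")
        if not self.bands:
            raise ValidationError("profile needs at least one band")

    # -- band bookkeeping --------------------------------------------------

    def bands_with_label(self, label: str) -> list[BandComponent]:
        return [b for b in self.bands if b.label == label]

    def band_amplitude(self, center: float, tol: float = 1.0) -> float:
        for b in self.bands:
            if abs(b.center - center) <= tol:
                return b.amplitude
        raise KeyError(f"no band at {center} cm-1 in profile {self.name!r}")

    def rate_percent(self, treatment: str) -> float:
        """Degradation fraction for a treatment, as the percent the study reports."""
        return 100.0 * self.degradation[treatment]

    def noiseless(self) -> "GenotypeProfile":
        return replace(self, amplitude_cv=0.0, gain_cv=0.0, additive_noise_frac=0.0)

    # -- spectral components -----------------------------------------------

    def background(self, w: np.ndarray) -> np.ndarray:
        span = w[-1] - w[0]
        u = 2.0 * (w - w[0]) / span - 1.0
        bg = np.polynomial.polynomial.polyval(u, np.asarray(self.background_poly))
        h, c, s = self.fluorescence
        return bg + h * np.exp(-((w - c) ** 2) / (2.0 * s**2))

    def band_sum(
        self,
        w: np.ndarray,
        carotenoid_scale: float = 1.0,
        anthocyanin_amplitude: float | None = None,
    ) -> np.ndarray:
        """Noise-free sum of all Raman bands.

        ``carotenoid_scale`` multiplies the carotenoid amplitudes;
        ``anthocyanin_amplitude`` overrides the profile's anthocyanin
        amplitude (used by the energy-balancing degradation model).
        """
        out = np.zeros_like(w)
        for b in self.bands:
            if b.label == "carotenoid":
                out += carotenoid_scale * b.profile(w)
            elif b.label == "anthocyanin" and anthocyanin_amplitude is not None:
                out += anthocyanin_amplitude * lorentzian(w, b.center, b.hwhm)
            else:
                out += b.profile(w)
        return out

    def max_band_height(self, w: np.ndarray) -> float:
        return float(self.band_sum(w).max())


@dataclass
class OsmoticKinetics:
    """Minute-scale carotenoid decay under mannitol osmotic stress.

    ``half_life_min`` maps mannitol concentration (mM) to the decay
    half-life (minutes); it must be strictly decreasing in concentration.
    ``floor`` is the residual amplitude fraction that never degrades;
    ``spatial_sd`` is the lognormal CV of persistent per-pixel carotenoid
    content across the mapped area.
    """

    half_life_min: dict[float, float]
    floor: float = 0.1
    spatial_sd: float = 0.08
    timepoints_min: tuple[float, ...] = (0.0, 5.0, 15.0, 30.0, 45.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.floor < 1.0:
            raise ValidationError("floor must be in [0, 1)")
        if self.spatial_sd < 0:
            raise ValidationError("spatial_sd must be >= 0")
        concs = sorted(self.half_life_min)
        hls = [self.half_life_min[c] for c in concs]
        if any(hls[i + 1] >= hls[i] for i in range(len(hls) - 1)):
            raise ValidationError(
                "half-life must be strictly decreasing in mannitol concentration"
            )

    def half_life(self, conc: float) -> float:
        for c, hl in self.half_life_min.items():
            if float(c) == float(conc):
                return hl
        raise ValidationError(
            f"unknown mannitol concentration {conc} mM; known: "
            f"{sorted(self.half_life_min)} (or 0 for the water control)"
        )

    def decay_fraction(self, conc: float, t_min: float) -> float:
        """Expected amplitude fraction remaining ``t_min`` minutes after stress."""
        if float(conc) == 0.0:
            return 1.0
        hl = self.half_life(conc)
        return self.floor + (1.0 - self.floor) * 2.0 ** (-t_min / hl)


@dataclass
class StudyDesign:
    """Replication structure of the in-vivo drought study."""

    genotypes: tuple[str, ...]
    treatments: tuple[str, ...] = ("control", "drought")
    replicates: int = 3
    plants: int = 5
    spectra_per_day: int = 12
    days: tuple[int, ...] = tuple(range(8))

    def __post_init__(self) -> None:
        days = list(self.days)
        if not days or days[0] != 0 or days != list(range(len(days))):
            raise ValidationError(
                f"days must form a contiguous range starting at 0, got {days}"
            )

    @property
    def n_spectra_per_genotype(self) -> int:
        return (
            len(self.treatments)
            * self.replicates
            * self.plants
            * len(self.days)
            * self.spectra_per_day
        )


# ---------------------------------------------------------------------------
# anthocyanin energy balance
# ---------------------------------------------------------------------------

def balanced_anthocyanin(
    profile: GenotypeProfile, carotenoid_scale: float, w: np.ndarray
) -> float:
    """Anthocyanin amplitude that keeps total band energy constant.

    Solves ``||s*C + b*H + F||^2 = ||C + b0*H + F||^2`` for ``b`` given the
    carotenoid scale ``s``, where C, H, F are the carotenoid, unit
    anthocyanin and remaining band shapes on the grid.  As carotenoids
    degrade (s < 1), b grows above the resting amplitude b0, emulating
    stress-induced anthocyanin accumulation at conserved spectral energy.
    """
    anth = profile.bands_with_label("anthocyanin")
    if not anth:
        raise ValidationError(
            f"profile {profile.name!r} has no anthocyanin band to balance"
        )
    b0 = sum(b.amplitude for b in anth)
    C = np.zeros_like(w)
    H = np.zeros_like(w)
    F = np.zeros_like(w)
    for b in profile.bands:
        if b.label == "carotenoid":
            C += b.profile(w)
        elif b.label == "anthocyanin":
            H += lorentzian(w, b.center, b.hwhm)
        else:
            F += b.profile(w)
    cc, hh, ff = C @ C, H @ H, F @ F
    ch, cf, hf = C @ H, C @ F, H @ F
    s = carotenoid_scale
    e0 = cc + b0**2 * hh + ff + 2.0 * (b0 * ch + cf + b0 * hf)
    beta = s * ch + hf
    gamma = s**2 * cc + 2.0 * s * cf + ff - e0
    disc = beta**2 - hh * gamma
    if disc < 0:  # cannot happen for s <= 1; guard for exotic inputs
        raise ValidationError("no anthocyanin amplitude balances band energy")
    return float((-beta + np.sqrt(disc)) / hh)


# ---------------------------------------------------------------------------
# single-spectrum generator
# ---------------------------------------------------------------------------

def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multiplier with the requested coefficient of variation."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def _synth_batch(
    profile: GenotypeProfile,
    n: int,
    rng: np.random.Generator,
    w: np.ndarray,
    scale: float = 1.0,
    carotenoid_scale: float | np.ndarray = 1.0,
    anthocyanin_amplitude: float | None = None,
    amplitude_noise: bool = True,
    gain_noise: bool = True,
) -> np.ndarray:
    """Generate ``n`` spectra as an ``(n, len(w))`` intensity matrix.

    ``carotenoid_scale`` may be a scalar or a per-spectrum ``(n,)`` vector
    (used for persistent per-pixel heterogeneity in map series).
    """
    bg = profile.background(w)
    car = np.zeros_like(w)
    rest = np.zeros_like(w)
    for b in profile.bands:
        if b.label == "carotenoid":
            car += b.profile(w)
        elif b.label == "anthocyanin" and anthocyanin_amplitude is not None:
            rest += anthocyanin_amplitude * lorentzian(w, b.center, b.hwhm)
        else:
            rest += b.profile(w)
    amp = (
        _lognormal_factor(rng, profile.amplitude_cv, n)
        if amplitude_noise
        else np.ones(n)
    )
    gain = _lognormal_factor(rng, profile.gain_cv, n) if gain_noise else np.ones(n)
    car_scale = np.broadcast_to(np.asarray(carotenoid_scale, float), (n,))
    bands = (
        (car_scale * amp)[:, None] * car[None, :] + rest[None, :]
    ) * scale
    Y = gain[:, None] * (bg[None, :] + bands)
    sd = profile.additive_noise_frac * profile.max_band_height(w) * scale
    if sd > 0:
        Y = Y + rng.normal(0.0, sd, size=Y.shape)
    return Y


def synth_spectrum(
    profile: GenotypeProfile,
    scale: float = 1.0,
    seed: int | None = None,
    wavenumbers: np.ndarray | None = None,
    carotenoid_scale: float = 1.0,
    meta: SampleMeta | None = None,
) -> Spectrum:
    """One synthetic spectrum: background + Lorentzian bands * scale + noise.

    Deterministic given ``seed``.  Set the profile's noise parameters to
    zero (:meth:`GenotypeProfile.noiseless`) for a noise-free trace.
    """
    if scale <= 0:
        raise ValidationError(f"scale must be positive, got {scale}")
    w = DEFAULT_WAVENUMBERS if wavenumbers is None else np.asarray(wavenumbers, float)
    rng = np.random.default_rng(seed)
    Y = _synth_batch(profile, 1, rng, w, scale=scale, carotenoid_scale=carotenoid_scale)
    m = meta or SampleMeta(
        sample_id=f"{profile.name}-synth", genotype=profile.name, tissue=profile.tissue
    )
    return Spectrum(w, Y[0], m)


def carotenoid_series(
    profile: GenotypeProfile,
    carotenoid_scales: Sequence[float],
    wavenumbers: np.ndarray | None = None,
) -> list[Spectrum]:
    """Noise-free spectra spanning a range of true carotenoid amplitudes.

    The anthocyanin band is energy-balanced at every scale, matching the
    study generator's degradation model; used to verify that the preprocessed
    1157 cm^-1 amplitude tracks true carotenoid content linearly.
    """
    w = DEFAULT_WAVENUMBERS if wavenumbers is None else np.asarray(wavenumbers, float)
    quiet = profile.noiseless()
    out = []
    for s in carotenoid_scales:
        b = balanced_anthocyanin(quiet, s, w)
        y = quiet.background(w) + quiet.band_sum(
            w, carotenoid_scale=s, anthocyanin_amplitude=b
        )
        out.append(
            Spectrum(
                w,
                y,
                SampleMeta(
                    sample_id=f"{profile.name}-cs{s:g}",
                    genotype=profile.name,
                    tissue=profile.tissue,
                    extras={"carotenoid_scale": float(s)},
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# study generator
# ---------------------------------------------------------------------------

def synth_study(
    profiles: Mapping[str, GenotypeProfile],
    design: StudyDesign | None = None,
    seed: int | None = 0,
) -> StudyDataset:
    """Simulate the full in-vivo drought study.

    Expected carotenoid amplitude declines linearly from A0 (day 0) to
    A0*(1-r) (final day) in each treatment arm, with per-spectrum lognormal
    amplitude and gain noise and additive detector noise.  Reproducible
    bit-for-bit for a given seed and design.
    """
    if design is None:
        design = StudyDesign(genotypes=tuple(profiles))
    for g in design.genotypes:
        if g not in profiles:
            raise ValidationError(f"no profile for genotype {g!r}")
    w = DEFAULT_WAVENUMBERS
    rng = np.random.default_rng(seed)
    d_end = max(design.days)
    records: dict = {}
    for gname in design.genotypes:
        prof = profiles[gname]
        for treatment in design.treatments:
            if treatment not in prof.degradation:
                raise ValidationError(
                    f"profile {gname!r} defines no degradation fraction for "
                    f"treatment {treatment!r}"
                )
            r = prof.degradation[treatment]
            has_anth = bool(prof.bands_with_label("anthocyanin"))
            for day in design.days:
                s_d = 1.0 - r * (day / d_end) if d_end > 0 else 1.0
                b_d = balanced_anthocyanin(prof, s_d, w) if has_anth else None
                n = design.replicates * design.plants * design.spectra_per_day
                Y = _synth_batch(
                    prof, n, rng, w, carotenoid_scale=s_d, anthocyanin_amplitude=b_d
                )
                i = 0
                for rep in range(1, design.replicates + 1):
                    for plant in range(1, design.plants + 1):
                        key = (gname, treatment, rep, plant, day)
                        specs = []
                        for k in range(design.spectra_per_day):
                            meta = SampleMeta(
                                sample_id=(
                                    f"{gname}-{treatment}-r{rep}-p{plant}"
                                    f"-d{day}-s{k}"
                                ),
                                genotype=gname,
                                treatment=treatment,
                                replicate=rep,
                                plant=plant,
                                day=day,
                                tissue=prof.tissue,
                            )
                            specs.append(Spectrum(w, Y[i], meta))
                            i += 1
                        records[key] = specs
    return StudyDataset(
        records,
        design={
            "genotypes": list(design.genotypes),
            "treatments": list(design.treatments),
            "replicates": design.replicates,
            "plants": design.plants,
            "spectra_per_day": design.spectra_per_day,
            "days": list(design.days),
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# mannitol map-series generator
# ---------------------------------------------------------------------------

def _grid_positions(grid: str) -> tuple[str, np.ndarray, tuple[int, int]]:
    if grid not in MAP_GRIDS:
        raise ValidationError(f"unknown map grid {grid!r}; known: {sorted(MAP_GRIDS)}")
    spec = MAP_GRIDS[grid]
    (nx, ny) = spec["shape"]
    ex, ey = spec["extent_um"]
    xs = np.linspace(0.0, ex, nx)
    ys = np.linspace(0.0, ey, ny)
    # row-major, x fastest: matches image-rendering convention
    pos = np.array([(x, y) for y in ys for x in xs])
    return spec["axes"], pos, (nx, ny)


def synth_map_series(
    kinetics: OsmoticKinetics,
    conc: float,
    grid: str = "XY80",
    timepoints: Sequence | None = None,
    seed: int | None = 0,
    profile: GenotypeProfile | None = None,
) -> list[SpectrumMap]:
    """Simulate a pre/post mannitol map series at one concentration.

    ``timepoints`` is a sequence of minutes with the string ``"pre"`` for the
    pre-treatment map (default ``("pre", 0, 5, 15, 30, 45)``).  ``conc`` must
    be 0 (deionized-water control) or a concentration in the kinetics table.
    Per-pixel carotenoid content is persistent across timepoints; decay
    applies on top of it.  White tissue does not decay.
    """
    if profile is None:
        profile = default_profiles()["B73"]
    if float(conc) != 0.0:
        kinetics.half_life(conc)  # validates
    if timepoints is None:
        timepoints = ("pre",) + tuple(kinetics.timepoints_min)
    axes, pos, shape = _grid_positions(grid)
    w = DEFAULT_WAVENUMBERS
    rng = np.random.default_rng(seed)
    n = len(pos)
    pixel = _lognormal_factor(rng, kinetics.spatial_sd, n)
    treatment = f"mannitol:{conc:g}"
    maps = []
    for tp in timepoints:
        is_pre = isinstance(tp, str) and tp == "pre"
        t = None if is_pre else float(tp)
        if is_pre or profile.tissue == "white":
            s = 1.0
        else:
            s = kinetics.decay_fraction(conc, t)
        Y = _synth_batch(
            profile,
            n,
            rng,
            w,
            carotenoid_scale=s * pixel,
            amplitude_noise=False,
            gain_noise=False,
        )
        spectra = []
        for i in range(n):
            meta = SampleMeta(
                sample_id=f"{profile.name}-{treatment}-{grid}-{'pre' if is_pre else f't{t:g}'}-px{i}",
                genotype=profile.name,
                treatment=treatment,
                minute=t,
                tissue=profile.tissue,
            )
            spectra.append(Spectrum(w, Y[i], meta))
        maps.append(
            SpectrumMap(
                axes=axes,
                positions=pos,
                spectra=spectra,
                grid_shape=shape,
                meta={
                    "spot_um": 2.0,
                    "power_mw": 2.0,
                    "integration_s": 0.5,
                    "mannitol_mm": float(conc),
                    "timepoint_min": t,
                    "is_pre": is_pre,
                    "tissue": profile.tissue,
                    "grid": grid,
                },
            )
        )
    return maps


# ---------------------------------------------------------------------------
# packaged default fixtures
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return (
        importlib.resources.files("ramanpheno").joinpath("data", name).read_text()
    )


def load_profiles(source: str) -> dict[str, GenotypeProfile]:
    """Parse a genotype-profile YAML document into profile objects."""
    doc = yaml.safe_load(source)
    profiles = {}
    for name, p in doc["profiles"].items():
        bands = [
            BandComponent(
                center=b["center"],
                hwhm=b["hwhm"],
                amplitude=b["amplitude"],
                label=b["label"],
            )
            for b in p["bands"]
        ]
        bg = p.get("background", {})
        fl = bg.get("fluorescence", {})
        profiles[name] = GenotypeProfile(
            name=name,
            tissue=p["tissue"],
            bands=bands,
            degradation={k: float(v) for k, v in p["degradation"].items()},
            amplitude_cv=float(p.get("amplitude_cv", 0.05)),
            gain_cv=float(p.get("gain_cv", 0.05)),
            additive_noise_frac=float(p.get("additive_noise_frac", 0.01)),
            background_poly=tuple(bg.get("poly", (3.0, 0.8, -0.5, 0.3))),
            fluorescence=(
                float(fl.get("height", 5.0)),
                float(fl.get("center", 1250.0)),
                float(fl.get("sigma", 300.0)),
            ),
        )
    return profiles


def load_kinetics(source: str) -> OsmoticKinetics:
    doc = yaml.safe_load(source)
    return OsmoticKinetics(
        half_life_min={float(k): float(v) for k, v in doc["half_life_min"].items()},
        floor=float(doc.get("floor", 0.1)),
        spatial_sd=float(doc.get("spatial_sd", 0.08)),
        timepoints_min=tuple(float(t) for t in doc.get("timepoints_min", (0, 5, 15, 30, 45))),
    )


def default_profiles() -> dict[str, GenotypeProfile]:
    """The packaged fixture table: five maize genotypes plus dark-grown tissue.

    Stressed degradation fractions encode the study's reported day-0 -> day-7
    rates (CML176 22%, OH28 20%, B73 6%; lox2 10%, lox4 3%); the
    near-isogenic lines share B73's initial band amplitudes while the inbreds
    differ; the white-tissue fixture has lower carotenoid amplitudes and no
    degradation under osmotic stress.
    """
    return load_profiles(_data_text("genotypes.yaml"))


def default_kinetics() -> OsmoticKinetics:
    """The packaged mannitol kinetics table (100/150/250 mM half-lives)."""
    return load_kinetics(_data_text("kinetics.yaml"))
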