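"""Degradation-rate statistics and group comparisons.

The drought-phenotyping statistic is the relative carotenoid degradation
rate over the study window,

    rate = 100 * (A(day 0) - A(day 7)) / A(day 0)   [percent],

computed on the preprocessed 1157 cm^-1 band amplitude.  Aggregation follows
the study's replication ladder: the twelve spectra per plant per day are
averaged, then the five plants per replicate, then the rate is computed per
replicate, and results are reported as mean +/- SE over the three replicate
experiments.  Group comparisons use classical one-way ANOVA at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mapping import band_intensity_map
from .preprocess import PreprocessParams, preprocess_matrix
from .quantify import BandDefinition, _band_slice, default_band
from .spectra import SpectrumMap, StudyDataset, ValidationError

__all__ = [
    "RateResult",
    "AnovaResult",
    "degradation_rate",
    "band_amplitude_table",
    "group_rates",
    "one_way_anova",
    "variance_homogeneity",
    "time_to_fraction",
]

ALPHA = 0.05


@dataclass
class RateResult:
    """Per-genotype, per-treatment degradation rate (percent) with SE."""

    genotype: str
    treatment: str
    rates: np.ndarray  # one rate per replicate, percent
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("rate result needs at least one replicate")
        if not np.isfinite(self.mean):
            raise ValidationError("rate is not finite")
        if self.se < 0:
            raise ValidationError("SE must be >= 0")


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    significant: bool

    def __post_init__(self) -> None:
        if self.f < 0 or not 0.0 <= self.p <= 1.0:
            raise ValidationError("invalid ANOVA result")


def degradation_rate(
    amplitudes_by_day: dict[int, float], d_start: int = 0, d_end: int = 7
) -> float:
    """Relative amplitude loss between two days, in percent.

    ``100 * (A(d_start) - A(d_end)) / A(d_start)``; negative if the
    amplitude rose.  Invariant to rescaling all amplitudes by c > 0.
    """
    for d in (d_start, d_end):
        if d not in amplitudes_by_day:
            raise ValidationError(f"day {d} missing from amplitude series")
    a0 = amplitudes_by_day[d_start]
    if a0 <= 0:
        raise ValidationError(
            f"amplitude at day {d_start} must be > 0, got {a0:g}"
        )
    return 100.0 * (a0 - amplitudes_by_day[d_end]) / a0


def band_amplitude_table(
    dataset: StudyDataset,
    band: BandDefinition | None = None,
    params: PreprocessParams | None = None,
    average_first: bool = True,
) -> pd.DataFrame:
    """Tabulate one band amplitude per (genotype, treatment, replicate,
    plant, day) cell of the study.

    With ``average_first=True`` (the default, matching the study's use of
    mean spectra averaged over leaf regions) the spectra of each cell are
    averaged on the raw scale before preprocessing, which suppresses
    detector noise ahead of the nonlinear baseline step.  With
    ``average_first=False`` every spectrum is preprocessed individually and
    the amplitudes are averaged instead.  All spectra must share one
    wavenumber grid; preprocessing runs as one vectorized pass.
    """
    band = band or default_band()
    params = params or PreprocessParams()
    keys, rows = [], []
    w = None
    for key in sorted(dataset.records):
        specs = dataset.records[key]
        for s in specs:
            if w is None:
                w = s.wavenumbers
            elif len(s.wavenumbers) != len(w) or not np.allclose(
                s.wavenumbers, w, rtol=1e-9, atol=1e-9
            ):
                raise ValidationError(
                    "band_amplitude_table requires a shared wavenumber grid"
                )
        if average_first:
            keys.append(key)
            rows.append(np.mean([s.intensities for s in specs], axis=0))
        else:
            for s in specs:
                keys.append(key)
                rows.append(s.intensities)
    Y = np.vstack(rows)
    processed, _, _ = preprocess_matrix(Y, w, params, normalize=True)
    sl = _band_slice(w, band)
    amps = processed[:, sl].max(axis=1)
    df = pd.DataFrame(
        keys, columns=["genotype", "treatment", "replicate", "plant", "day"]
    )
    df["amplitude"] = amps
    if not average_first:
        df = (
            df.groupby(["genotype", "treatment", "replicate", "plant", "day"])[
                "amplitude"
            ]
            .mean()
            .reset_index()
        )
    return df


def group_rates(
    dataset: StudyDataset,
    band: BandDefinition | None = None,
    params: PreprocessParams | None = None,
    d_start: int = 0,
    d_end: int = 7,
    average_first: bool = True,
) -> list[RateResult]:
    """Degradation rate per genotype x treatment via the replication ladder.

    Per plant per day: one amplitude from the plant's mean spectrum (or the
    mean of per-spectrum amplitudes, see :func:`band_amplitude_table`); per
    replicate: mean over plants; rate per replicate from the day d_start ->
    d_end relative change; reported as mean +/- SE over replicates.
    """
    df = band_amplitude_table(dataset, band, params, average_first)
    if df.empty:
        raise ValidationError("empty dataset")
    for d in (d_start, d_end):
        if d not in set(df["day"]):
            raise ValidationError(f"day {d} missing from dataset")
    rep_means = (
        df.groupby(["genotype", "treatment", "replicate", "day"])["amplitude"]
        .mean()
        .unstack("day")
    )
    results = []
    for (genotype, treatment), sub in rep_means.groupby(
        ["genotype", "treatment"]
    ):
        rates = np.array(
            [
                degradation_rate(
                    {d: row[d] for d in sub.columns if not np.isnan(row[d])},
                    d_start,
                    d_end,
                )
                for _, row in sub.iterrows()
            ]
        )
        n = len(rates)
        se = float(np.std(rates, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        results.append(
            RateResult(
                genotype=genotype,
                treatment=treatment,
                rates=rates,
                mean=float(rates.mean()),
                se=se,
                n=n,
            )
        )
    return results


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Classical one-way ANOVA: F from between/within mean squares.

    Requires at least two groups with at least two values each; the p-value
    comes from the F distribution and the significance flag uses alpha=0.05.
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    groups = [np.asarray(g, float) for g in groups]
    for g in groups:
        if len(g) < 2:
            raise ValidationError("every ANOVA group needs at least two values")
    f, p = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    if not np.isfinite(f):  # all values identical in every group
        f, p = 0.0, 1.0
    return AnovaResult(
        f=float(f),
        df_between=k - 1,
        df_within=n - k,
        p=float(p),
        significant=bool(p < ALPHA),
    )


def variance_homogeneity(groups: list[np.ndarray]) -> tuple[float, float]:
    """Bartlett test of equal variances across replicate experiments.

    Offered as an optional diagnostic for the homogeneity assumption behind
    pooling replicates; returns ``(statistic, p_value)``.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    stat, p = sps.bartlett(*[np.asarray(g, float) for g in groups])
    return float(stat), float(p)


def time_to_fraction(
    map_series: list[SpectrumMap],
    band: BandDefinition | None = None,
    fraction: float = 0.5,
    params: PreprocessParams | None = None,
) -> float | None:
    """First post-treatment timepoint at which the map-mean band amplitude
    falls to <= ``fraction`` of the pre-treatment mean.

    Returns the timepoint in minutes, or ``None`` if the threshold is never
    reached within the series.  The series must contain at least one
    pre-treatment map.
    """
    band = band or default_band()
    pre_means, post = [], []
    for m in map_series:
        imap = band_intensity_map(m, band, params)
        mean = float(np.mean(imap.values))
        if m.is_pre:
            pre_means.append(mean)
        else:
            if m.timepoint_min is None:
                raise ValidationError("post-treatment map lacks a timepoint")
            post.append((float(m.timepoint_min), mean))
    if not pre_means:
        raise ValidationError("map series contains no pre-treatment map")
    threshold = fraction * float(np.mean(pre_means))
    for t, mean in sorted(post):
        if mean <= threshold:
            return t
    return None
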