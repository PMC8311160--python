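"""Spectral preprocessing: baseline removal, smoothing, normalization.

The chain mirrors standard practice for in-vivo plant Raman spectra, where
broad tissue autofluorescence dominates the raw signal:

1. **Iterative polynomial ("modified polyfit") baseline removal** — a
   polynomial of fixed order is least-squares fitted to the trace; every
   point lying above the fit is clamped down to the fit value; the fit is
   repeated on the clamped trace until it stops moving.  The converged fit
   tracks the lower envelope of the spectrum (the fluorescence background
   under the Raman bands) and is subtracted.
2. **Savitzky–Golay smoothing** — local least-squares polynomial smoothing
   (15-point window, cubic) that suppresses detector noise while preserving
   band shape up to the polynomial order.
3. **Unit-vector normalization** — division by the Euclidean norm over the
   analysis range, removing acquisition-to-acquisition intensity scale
   (laser-power drift, focus).

Polynomial fits use a Chebyshev basis on a scaled domain for conditioning;
the fitted values are identical to an ordinary power-basis least-squares fit
of the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum, ValidationError

__all__ = [
    "PreprocessParams",
    "baseline_correct",
    "savgol_smooth",
    "unit_vector_normalize",
    "preprocess_spectrum",
    "baseline_correct_matrix",
    "preprocess_matrix",
]


@dataclass
class PreprocessParams:
    """Tunable parameters of the preprocessing chain.

    ``baseline_tol_frac`` is relative: convergence is declared when the
    maximum absolute change between successive polynomial fits falls below
    ``baseline_tol_frac * (max - min)`` of the raw trace.
    """

    baseline_order: int = 7
    baseline_max_iter: int = 100
    baseline_tol_frac: float = 1e-6
    sg_window: int = 15
    sg_order: int = 3
    # None means the full wavenumber grid
    norm_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.baseline_order < 1:
            raise ValidationError("baseline polynomial order must be >= 1")
        if self.baseline_max_iter < 1:
            raise ValidationError("baseline max iterations must be >= 1")
        if self.baseline_tol_frac <= 0:
            raise ValidationError("baseline tolerance must be > 0")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValidationError(
                "Savitzky-Golay window must be odd and greater than the "
                f"polynomial order (window={self.sg_window}, order={self.sg_order})"
            )


def _chebyshev_design(wavenumbers: np.ndarray, order: int) -> np.ndarray:
    span = wavenumbers[-1] - wavenumbers[0]
    x = 2.0 * (wavenumbers - wavenumbers[0]) / span - 1.0
    return np.polynomial.chebyshev.chebvander(x, order)


def baseline_correct_matrix(
    Y: np.ndarray, wavenumbers: np.ndarray, params: PreprocessParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Modified-polyfit baseline removal for a stack of spectra.

    Parameters
    ----------
    Y : (n_spectra, n_points) raw intensities, all on ``wavenumbers``.

    Returns ``(corrected, baseline, converged)`` where ``converged`` is a
    boolean flag per spectrum (non-convergence within the iteration budget is
    reported, not raised).
    """
    params = params or PreprocessParams()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, m = Y.shape
    if m < params.baseline_order + 2:
        raise ValidationError(
            f"need at least order+2 = {params.baseline_order + 2} points for "
            f"baseline fitting, got {m}"
        )
    D = _chebyshev_design(wavenumbers, params.baseline_order)
    # shared grid -> one pseudo-inverse serves every spectrum and iteration
    pinv = np.linalg.pinv(D)

    rng = Y.max(axis=1) - Y.min(axis=1)
    tol = params.baseline_tol_frac * np.where(rng > 0, rng, 1.0)

    work = Y.copy()
    fit = (D @ (pinv @ work.T)).T
    converged = np.zeros(n, dtype=bool)
    for _ in range(params.baseline_max_iter - 1):
        work = np.minimum(work, fit)
        new_fit = (D @ (pinv @ work.T)).T
        delta = np.abs(new_fit - fit).max(axis=1)
        fit = new_fit
        converged = delta < tol
        if converged.all():
            break
    return Y - fit, fit, converged


def baseline_correct(
    spectrum: Spectrum, params: PreprocessParams | None = None
) -> tuple[Spectrum, Spectrum]:
    """Remove the autofluorescence baseline from one spectrum.

    Returns ``(corrected, baseline)``.  The corrected spectrum carries a
    ``baseline_converged`` flag in its metadata extras; non-convergence
    within the iteration budget sets it to ``False`` instead of raising.
    """
    corrected, baseline, conv = baseline_correct_matrix(
        spectrum.intensities[None, :], spectrum.wavenumbers, params
    )
    corr = spectrum.with_intensities(corrected[0], baseline_converged=bool(conv[0]))
    base = spectrum.with_intensities(baseline[0])
    return corr, base


def _require_uniform(spectrum: Spectrum) -> None:
    if spectrum.uniform_step is None:
        raise ValidationError(
            "Savitzky-Golay smoothing requires a uniform wavenumber grid; "
            "resample the spectrum first"
        )


def savgol_smooth(
    spectrum: Spectrum, params: PreprocessParams | None = None
) -> Spectrum:
    """Savitzky–Golay smoothing (default 15-point window, cubic, mirror edges)."""
    params = params or PreprocessParams()
    _require_uniform(spectrum)
    if params.sg_window > len(spectrum.intensities):
        raise ValidationError(
            f"Savitzky-Golay window {params.sg_window} exceeds spectrum length "
            f"{len(spectrum.intensities)}"
        )
    out = savgol_filter(
        spectrum.intensities, params.sg_window, params.sg_order, mode="mirror"
    )
    return spectrum.with_intensities(out)


def unit_vector_normalize(
    spectrum: Spectrum, norm_range: tuple[float, float] | None = None
) -> Spectrum:
    """Scale the trace so its Euclidean norm over ``norm_range`` equals 1."""
    w = spectrum.wavenumbers
    if norm_range is None:
        mask = slice(None)
    else:
        lo, hi = norm_range
        mask = (w >= lo) & (w <= hi)
        if not np.any(mask):
            raise ValidationError(
                f"normalization range {norm_range} contains no grid points"
            )
    norm = float(np.linalg.norm(spectrum.intensities[mask]))
    if norm == 0.0:
        raise ValidationError("cannot unit-normalize a zero spectrum")
    return spectrum.with_intensities(spectrum.intensities / norm)


def preprocess_matrix(
    Y: np.ndarray,
    wavenumbers: np.ndarray,
    params: PreprocessParams | None = None,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full preprocessing chain applied to a stack of spectra at once.

    Vectorized equivalent of :func:`preprocess_spectrum` applied row-wise
    (used by the study-level and map-level pipelines, where thousands of
    spectra share one grid).  Returns ``(processed, baseline, converged)``.
    """
    params = params or PreprocessParams()
    d = np.diff(wavenumbers)
    if len(d) and not np.allclose(d, d[0], rtol=1e-8, atol=1e-10 * abs(d[0])):
        raise ValidationError(
            "preprocessing requires a uniform wavenumber grid; resample first"
        )
    corrected, baseline, converged = baseline_correct_matrix(Y, wavenumbers, params)
    if params.sg_window > corrected.shape[1]:
        raise ValidationError("Savitzky-Golay window exceeds spectrum length")
    smoothed = savgol_filter(
        corrected, params.sg_window, params.sg_order, axis=1, mode="mirror"
    )
    if not normalize:
        return smoothed, baseline, converged
    if params.norm_range is None:
        mask = slice(None)
    else:
        lo, hi = params.norm_range
        mask = (wavenumbers >= lo) & (wavenumbers <= hi)
    norms = np.linalg.norm(smoothed[:, mask], axis=1)
    if np.any(norms == 0.0):
        raise ValidationError("cannot unit-normalize a zero spectrum")
    return smoothed / norms[:, None], baseline, converged


def preprocess_spectrum(
    spectrum: Spectrum,
    params: PreprocessParams | None = None,
    normalize: bool = True,
) -> Spectrum:
    """Baseline removal, then smoothing, then unit-vector normalization.

    Processing provenance (the parameter set and the baseline convergence
    flag) is recorded in the output metadata extras.
    """
    params = params or PreprocessParams()
    processed, _, converged = preprocess_matrix(
        spectrum.intensities[None, :], spectrum.wavenumbers, params, normalize
    )
    return spectrum.with_intensities(
        processed[0],
        preprocess=asdict(params),
        baseline_converged=bool(converged[0]),
        normalized=normalize,
    )
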