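"""Band-intensity images from spectrum maps, and their summaries.

Raman images are built from the height of the carotenoid 1157 cm^-1 band at
each sampled point.  Per-pixel preprocessing applies baseline removal and
smoothing but **not** unit-vector normalization: maps compare absolute band
heights across pixels and timepoints, and per-pixel normalization would
erase exactly the intensity loss the images are meant to show.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import PreprocessParams, preprocess_matrix
from .quantify import BandDefinition, _band_slice
from .spectra import SpectrumMap, ValidationError

__all__ = ["IntensityMap", "band_intensity_map", "map_summary", "render_map"]


@dataclass
class IntensityMap:
    """One band-amplitude value per sampled map point."""

    axes: str
    positions: np.ndarray
    values: np.ndarray
    band: str
    grid_shape: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.values = np.asarray(self.values, float)
        if len(self.values) != len(self.positions):
            raise ValidationError(
                f"{len(self.values)} values for {len(self.positions)} positions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("intensity map contains non-finite values")

    @property
    def n_points(self) -> int:
        return len(self.values)

    def as_image(self) -> np.ndarray:
        """Reshape values to a (rows, cols) image; requires a regular grid."""
        if self.grid_shape is None:
            raise ValidationError("map has no regular grid shape to reshape to")
        nx, ny = self.grid_shape
        return self.values.reshape(ny, nx)


def band_intensity_map(
    smap: SpectrumMap,
    band: BandDefinition,
    params: PreprocessParams | None = None,
) -> IntensityMap:
    """Preprocess each map spectrum (baseline + smoothing, no normalization)
    and evaluate the band amplitude at every sampled point."""
    Y = smap.intensity_matrix()
    processed, _, _ = preprocess_matrix(
        Y, smap.wavenumbers, params, normalize=False
    )
    sl = _band_slice(smap.wavenumbers, band)
    values = processed[:, sl].max(axis=1)
    return IntensityMap(
        axes=smap.axes,
        positions=smap.positions,
        values=values,
        band=band.name,
        grid_shape=smap.grid_shape,
        meta=dict(smap.meta),
    )


def map_summary(maps: list[IntensityMap]) -> tuple[float, float, int]:
    """Pooled mean, sample SD and total point count over all map points.

    Matches the study's histogram convention (e.g. n = 80 points x 3
    replicates x 2 series for XY maps).
    """
    if not maps:
        raise ValidationError("map_summary needs at least one map")
    bands = {m.band for m in maps}
    if len(bands) > 1:
        raise ValidationError(f"maps quantify different bands: {sorted(bands)}")
    values = np.concatenate([m.values for m in maps])
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    return float(values.mean()), sd, n


def render_map(imap: IntensityMap, path, vmin=None, vmax=None) -> None:
    """Write a false-color raster of the intensity map with a scale bar.

    Nearest-neighbor pixels (the sampling grids are sparse: 80 points over
    180 x 140 um); deterministic for fixed input.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    img = imap.as_image()
    x = imap.positions[:, 0]
    y = imap.positions[:, 1]
    extent = (x.min(), x.max(), y.max(), y.min())  # origin top-left, y downward
    fig, ax = plt.subplots(figsize=(4, 3.2))
    im = ax.imshow(
        img,
        cmap="viridis",
        interpolation="nearest",
        extent=extent,
        vmin=vmin,
        vmax=vmax,
        aspect="auto",
    )
    fig.colorbar(im, ax=ax, label=f"{imap.band} amplitude (a.u.)")
    # 50 um scale bar, bottom-left
    x0 = x.min() + 0.05 * (x.max() - x.min())
    y0 = y.max() - 0.08 * (y.max() - y.min())
    ax.plot([x0, x0 + 50.0], [y0, y0], color="white", lw=3)
    ax.text(x0, y0 - 0.04 * (y.max() - y.min()), "50 µm", color="white")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel(("y" if imap.axes == "XY" else "z") + " (µm)")
    t = imap.meta.get("timepoint_min")
    label = "pre" if imap.meta.get("is_pre") else (f"{t:g} min" if t is not None else "")
    conc = imap.meta.get("mannitol_mm")
    title = f"{imap.band}" + (f", {conc:g} mM" if conc is not None else "")
    ax.set_title(f"{title} {label}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
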