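"""Reading and writing spectra, spectrum maps and study manifests.

One long-form CSV dialect serves both point spectra and maps: columns
``sample_id, genotype, treatment, replicate, plant, day_or_min, phase,
tissue, x_um, y_um, z_um, wavenumber_cm1, intensity`` (UTF-8, comma
separator, "." decimal).  Point-spectrum files leave the coordinate columns
empty; map files fill ``x_um`` and either ``y_um`` (XY maps) or ``z_um``
(XZ maps) and hold exactly one map on one shared wavenumber grid.  Map files
additionally carry acquisition metadata in a single ``# meta: {...}`` JSON
comment line so that maps round-trip losslessly.  Numbers are serialized
with 12 significant digits.

A study manifest is a JSON file listing data files (paths relative to the
manifest) and the study design.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import (
    FormatError,
    SampleMeta,
    Spectrum,
    SpectrumMap,
    StudyDataset,
    ValidationError,
)

__all__ = ["read_spectra", "write_spectra", "read_manifest", "write_manifest",
           "dataset_from_spectra"]

COLUMNS = [
    "sample_id",
    "genotype",
    "treatment",
    "replicate",
    "plant",
    "day_or_min",
    "phase",
    "tissue",
    "x_um",
    "y_um",
    "z_um",
    "wavenumber_cm1",
    "intensity",
]

_FLOAT_FMT = "%.12g"


def _opt(v, cast=float):
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return cast(v)


def _meta_to_row(meta: SampleMeta, is_map: bool) -> dict:
    day_or_min = meta.minute if is_map else meta.day
    return {
        "sample_id": meta.sample_id,
        "genotype": meta.genotype or "",
        "treatment": meta.treatment or "",
        "replicate": "" if meta.replicate is None else meta.replicate,
        "plant": "" if meta.plant is None else meta.plant,
        "day_or_min": "" if day_or_min is None else day_or_min,
        "phase": "",
        "tissue": meta.tissue or "",
    }


def write_spectra(objects, path, format: str = "csv") -> None:
    """Serialize spectra (``format="csv"``) or one map (``format="map_csv"``).

    An empty spectrum list produces a header-only file.  Writing a map whose
    member spectra are not all on one wavenumber grid raises
    :class:`ValidationError`.
    """
    path = Path(path)
    if format == "csv":
        spectra = list(objects)
        rows = []
        for s in spectra:
            base = _meta_to_row(s.meta, is_map=False)
            for wn, it in zip(s.wavenumbers, s.intensities):
                rows.append({**base, "x_um": "", "y_um": "", "z_um": "",
                             "wavenumber_cm1": wn, "intensity": it})
        df = pd.DataFrame(rows, columns=COLUMNS)
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif format == "map_csv":
        smap = objects
        if not isinstance(smap, SpectrumMap):
            raise ValidationError("map_csv format expects a SpectrumMap")
        smap.validate()  # raises on mixed grids / duplicate positions
        second = "y_um" if smap.axes == "XY" else "z_um"
        rows = []
        for (p, s) in zip(smap.positions, smap.spectra):
            base = _meta_to_row(s.meta, is_map=True)
            base["phase"] = "pre" if smap.is_pre else "post"
            for wn, it in zip(s.wavenumbers, s.intensities):
                row = {**base, "x_um": p[0], "y_um": "", "z_um": "",
                       "wavenumber_cm1": wn, "intensity": it}
                row[second] = p[1]
                rows.append(row)
        df = pd.DataFrame(rows, columns=COLUMNS)
        header = {
            "axes": smap.axes,
            "grid_shape": list(smap.grid_shape) if smap.grid_shape else None,
            "meta": smap.meta,
        }
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# meta: " + json.dumps(header) + "\n")
            df.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    else:
        raise ValidationError(f"unknown format {format!r}")


def _row_meta(first: pd.Series, is_map: bool) -> SampleMeta:
    day_or_min = _opt(first["day_or_min"])
    return SampleMeta(
        sample_id=str(first["sample_id"]),
        genotype=_opt(first["genotype"], str),
        treatment=_opt(first["treatment"], str),
        replicate=_opt(first["replicate"], lambda v: int(float(v))),
        plant=_opt(first["plant"], lambda v: int(float(v))),
        day=None if is_map or day_or_min is None else int(day_or_min),
        minute=day_or_min if is_map else None,
        tissue=_opt(first["tissue"], str),
    )


def _check_monotonic(wn: np.ndarray, row_index: np.ndarray, path) -> None:
    d = np.diff(wn)
    if len(d) and not np.all(d > 0):
        bad = int(np.argmin(d > 0)) + 1
        raise FormatError(
            f"{path}: wavenumber column not strictly increasing at data row "
            f"{int(row_index[bad]) + 2}"  # +2: 1-based and header line
        )


def read_spectra(path, format: str = "csv"):
    """Parse a spectra CSV into ``list[Spectrum]`` or a ``SpectrumMap``.

    Raises :class:`FormatError` (naming the first offending row) for a
    non-monotonic wavenumber column, and :class:`ValidationError` for
    unknown treatment labels or inconsistent map grids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = None
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# meta:"):
            header = json.loads(first[len("# meta:"):])
    df = pd.read_csv(path, comment="#", dtype={"sample_id": str}, skip_blank_lines=True)
    missing = [c for c in ("sample_id", "wavenumber_cm1", "intensity") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    for c in COLUMNS:
        if c not in df.columns:
            df[c] = np.nan

    if format == "csv":
        spectra = []
        if df.empty:
            return spectra
        for sid, sub in df.groupby("sample_id", sort=False):
            wn = sub["wavenumber_cm1"].to_numpy(float)
            _check_monotonic(wn, sub.index.to_numpy(), path)
            meta = _row_meta(sub.iloc[0], is_map=False)
            spectra.append(Spectrum(wn, sub["intensity"].to_numpy(float), meta))
        return spectra

    if format == "map_csv":
        if df.empty:
            raise FormatError(f"{path}: map file contains no data rows")
        axes = header["axes"] if header else ("XZ" if df["z_um"].notna().any() else "XY")
        second = "y_um" if axes == "XY" else "z_um"
        positions, spectra = [], []
        grid = None
        for (sid, x, y2), sub in df.groupby(
            ["sample_id", "x_um", second], sort=False
        ):
            wn = sub["wavenumber_cm1"].to_numpy(float)
            _check_monotonic(wn, sub.index.to_numpy(), path)
            if grid is None:
                grid = wn
            elif len(wn) != len(grid):
                raise FormatError(
                    f"{path}: spectrum {sid!r} has {len(wn)} points, expected "
                    f"{len(grid)} (length mismatch)"
                )
            meta = _row_meta(sub.iloc[0], is_map=True)
            positions.append((float(x), float(y2)))
            spectra.append(Spectrum(wn, sub["intensity"].to_numpy(float), meta))
        mmeta = header.get("meta", {}) if header else {}
        shape = tuple(header["grid_shape"]) if header and header.get("grid_shape") else None
        return SpectrumMap(
            axes=axes,
            positions=np.array(positions),
            spectra=spectra,
            grid_shape=shape,
            meta=mmeta,
        )

    raise ValidationError(f"unknown format {format!r}")


def dataset_from_spectra(spectra: list[Spectrum], design: dict | None = None) -> StudyDataset:
    """Assemble point spectra into a StudyDataset keyed by their metadata."""
    records: dict = {}
    for s in spectra:
        m = s.meta
        if None in (m.genotype, m.treatment, m.replicate, m.plant, m.day):
            raise ValidationError(
                f"spectrum {m.sample_id!r} lacks complete study metadata"
            )
        key = (m.genotype, m.treatment, m.replicate, m.plant, m.day)
        records.setdefault(key, []).append(s)
    return StudyDataset(records, design or {})


def write_manifest(path, files: list[dict], design: dict | None = None) -> None:
    """Write a study manifest: file entries (path, format) plus the design."""
    doc = {"files": files, "design": design or {}}
    Path(path).write_text(json.dumps(doc, indent=2))


def read_manifest(path):
    """Load every file listed in a manifest; paths resolve relative to it.

    Returns ``(objects, design)`` where ``objects`` is a list of the loaded
    spectra lists / maps in manifest order.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    objects = []
    for entry in doc.get("files", []):
        fpath = path.parent / entry["path"]
        objects.append(read_spectra(fpath, entry.get("format", "csv")))
    return objects, doc.get("design", {})
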