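"""Readers and writers for the formats the pipeline touches.

Images travel as continuous-mode imzML (via pyimzml) with a small JSON
sidecar (``<name>.meta.json``) carrying the physical geometry and polarity,
which the imzML writer itself cannot embed.  Peak tables travel as a pair of
CSV files: ``<name>`` holds samples x ions, ``<stem>.ions.csv`` holds the
ion annotations and classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from simscape.image import SpectralImage

_META_COLUMNS = ("sample_id", "group", "animal", "replicate")


# ---------------------------------------------------------------------------
# imzML


def write_imzml(image: SpectralImage, path) -> None:
    """Write a SpectralImage as continuous-mode imzML plus a geometry sidecar.

    Intensities are stored as float64 so counts round-trip exactly.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if image.n_channels == 0:
        raise ValueError("cannot write an image with zero channels")
    path = Path(path)
    with ImzMLWriter(
        str(path),
        mode="continuous",
        intensity_dtype=np.float64,
        polarity=image.polarity,
    ) as writer:
        for y in range(image.height_px):
            for x in range(image.width_px):
                writer.addSpectrum(
                    image.mz_axis, image.counts[y, x, :], (x + 1, y + 1, 1)
                )
    sidecar = {
        "pixel_size_um": image.pixel_size_um,
        "polarity": image.polarity,
        "metadata": {k: v for k, v in image.metadata.items()
                     if isinstance(v, (str, int, float, bool))},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_imzml(path, pixel_size_um: float | None = None) -> SpectralImage:
    """Read a continuous-mode imzML file on a full rectangular pixel grid.

    Geometry and polarity come from the JSON sidecar when present;
    otherwise ``pixel_size_um`` must be supplied (default 1.0 with a
    metadata flag) and polarity defaults to negative.  Processed-mode files
    (per-pixel m/z axes) and grids with missing pixels are rejected.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = ImzMLParser(str(path))
    coords = [(c[0], c[1]) for c in parser.coordinates]
    if not coords:
        raise ValueError(f"{path}: file contains no spectra")
    xs = sorted({c[0] for c in coords})
    ys = sorted({c[1] for c in coords})
    width, height = len(xs), len(ys)
    if len(set(coords)) != len(coords):
        raise ValueError(f"{path}: duplicate pixel coordinates")
    expected = {(x, y) for x in xs for y in ys}
    missing = expected - set(coords)
    if missing:
        raise ValueError(
            f"{path}: non-rectangular grid — missing pixel at grid index "
            f"{sorted(missing)[0]} of the {width}x{height} extent"
        )

    x_of = {x: i for i, x in enumerate(xs)}
    y_of = {y: i for i, y in enumerate(ys)}
    mz0, _ = parser.getspectrum(0)
    counts = np.zeros((height, width, len(mz0)), dtype=float)
    for i, (x, y) in enumerate(coords):
        mz, inten = parser.getspectrum(i)
        if len(mz) != len(mz0) or not np.array_equal(mz, mz0):
            raise ValueError(
                f"{path}: spectra do not share one m/z axis "
                "(processed-mode imzML is unsupported)"
            )
        counts[y_of[y], x_of[x], :] = inten

    sidecar_file = _sidecar_path(path)
    polarity = "negative"
    metadata: dict = {}
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())
        pixel_size_um = float(sidecar["pixel_size_um"])
        polarity = sidecar.get("polarity", "negative")
        metadata = dict(sidecar.get("metadata", {}))
    elif pixel_size_um is None:
        pixel_size_um = 1.0
        metadata["pixel_size_assumed"] = True
    return SpectralImage(
        mz_axis=np.asarray(mz0, dtype=float),
        counts=counts,
        pixel_size_um=pixel_size_um,
        polarity=polarity,
        metadata=metadata,
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


# ---------------------------------------------------------------------------
# Peak tables


@dataclass
class PeakTable:
    """Samples x ions matrix of TIC-normalised ROI-averaged intensities.

    ``meta`` holds one row per sample (sample_id index; group, animal and —
    before replicate aggregation — replicate columns).  ``values`` shares
    the index and has one float column per ion keyed by m/z.  ``ions`` is
    indexed by m/z with annotation and ion_class columns.
    """

    meta: pd.DataFrame
    values: pd.DataFrame
    ions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.meta.index.duplicated().any():
            dup = self.meta.index[self.meta.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the sample index")
        vals = self.values.to_numpy()
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("peak table contains non-finite values")
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("TIC-normalised intensities must lie in [0, 1]")
        # canonical ion order: ascending m/z
        order = sorted(self.values.columns, key=float)
        self.values = self.values[order]
        if not self.ions.empty:
            self.ions = self.ions.loc[[float(c) for c in order]]

    @property
    def mz(self) -> np.ndarray:
        return np.array([float(c) for c in self.values.columns])

    def group_values(self, mz: float) -> dict[str, np.ndarray]:
        """Per-group value arrays for one ion, in meta group order."""
        col = self.values[mz]
        return {
            g: col[self.meta["group"] == g].to_numpy()
            for g in pd.unique(self.meta["group"])
        }

    def ion_class_of(self, mz: float) -> str:
        if self.ions.empty or mz not in self.ions.index:
            return "other"
        return str(self.ions.loc[mz, "ion_class"])


def write_peak_table(table: PeakTable, path) -> None:
    """Write a peak table as CSV (+ ``<stem>.ions.csv`` ion sidecar).

    Metadata columns come first, ion columns in ascending m/z, values at 12
    significant digits so a read-back is lossless at that precision.
    """
    path = Path(path)
    out = table.meta.reset_index()
    if "sample_id" not in out.columns:
        out = out.rename(columns={"index": "sample_id"})
    for col in table.values.columns:
        out[_format_mz(col)] = table.values[col].to_numpy()
    out.to_csv(path, index=False, float_format="%.12g")
    if not table.ions.empty:
        ions = table.ions.reset_index()
        ions.to_csv(_ions_sidecar(path), index=False, float_format="%.12g")


def read_peak_table(path) -> PeakTable:
    """Read a peak table CSV written by :func:`write_peak_table`.

    Columns other than the known metadata columns are interpreted as ion
    m/z values.  Errors carry the offending row/column address.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    if "sample_id" not in raw.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    if raw["sample_id"].duplicated().any():
        dup = raw.loc[raw["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    meta_cols = [c for c in _META_COLUMNS if c in raw.columns]
    ion_cols = [c for c in raw.columns if c not in meta_cols]
    for c in ion_cols:
        try:
            float(c)
        except ValueError:
            raise ValueError(
                f"{path}: column {c!r} is neither sample metadata nor a "
                "numeric ion m/z"
            ) from None
    meta = raw[meta_cols].set_index("sample_id")
    if "replicate" in meta.columns:
        meta["replicate"] = meta["replicate"].astype(int)
    values = pd.DataFrame(index=meta.index)
    for c in ion_cols:
        col = pd.to_numeric(raw[c], errors="coerce")
        if col.isna().any():
            row = raw.loc[col.isna(), "sample_id"].iloc[0]
            raise ValueError(
                f"{path}: non-numeric value in column {c!r}, row "
                f"sample_id={row!r}"
            )
        values[float(c)] = col.to_numpy()
    values.columns = pd.Index([float(c) for c in values.columns], dtype=float)

    ions_path = _ions_sidecar(path)
    ions = pd.DataFrame()
    if ions_path.exists():
        ions = pd.read_csv(ions_path).set_index("mz")
    return PeakTable(meta=meta, values=values, ions=ions)


def _ions_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".ions.csv")


def _format_mz(mz: float) -> str:
    return f"{float(mz):.12g}"


# ---------------------------------------------------------------------------
# YAML configs


def load_config(path) -> dict:
    """Load a YAML run configuration as a plain dict."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level of the config must be a mapping")
    return cfg
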