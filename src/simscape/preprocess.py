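"""From raw images to the TIC-normalised peak table.

Stages: internal mass calibration against low-mass reference ions, central
region-of-interest extraction, peak integration over fixed m/z windows,
normalisation to the total ion count, and aggregation of technical
replicates to animal level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from simscape.image import SpectralImage
from simscape.io import PeakTable
from simscape.synthetic import CALIBRATION_REFERENCE_MZ, IonSpec

#: Maximum post-fit residual considered acceptable (ppm).
MAX_RESIDUAL_PPM = 300.0

#: Default (expected m/z, search tolerance in Th) calibration references:
#: H-, C-, CH-, C2-, C3-.
DEFAULT_CALIBRATION_REFS = tuple((mz, 0.5) for mz in CALIBRATION_REFERENCE_MZ)


@dataclass
class CalibrationResult:
    """Outcome of one image's mass-axis calibration."""

    applied: bool
    residual_ppm: dict[float, float] = dc_field(default_factory=dict)
    passed: bool = True
    message: str = ""

    @property
    def max_abs_residual_ppm(self) -> float:
        if not self.residual_ppm:
            return float("nan")
        return float(max(abs(v) for v in self.residual_ppm.values()))


def calibrate_mass_axis(
    image: SpectralImage,
    refs: Sequence[tuple[float, float]] = DEFAULT_CALIBRATION_REFS,
    degree: int = 1,
) -> tuple[SpectralImage, CalibrationResult]:
    """Internally calibrate the m/z axis against reference peaks.

    For each reference the observed position is the most intense channel of
    the mean spectrum within the reference's search tolerance.  A
    least-squares polynomial (default degree 1) is fitted in sqrt(m/z)
    space — time of flight is proportional to sqrt(m/z) — mapping observed
    to expected positions, and applied to the whole axis.

    Returns the calibrated image and a :class:`CalibrationResult` with the
    post-fit residual in ppm at every found reference.  With fewer than two
    detectable references calibration is skipped (warning flag); any
    residual above 300 ppm marks the image as failing validation.
    """
    spectrum = image.mean_spectrum()
    observed, expected = [], []
    for mz_ref, tol in refs:
        mask = np.abs(image.mz_axis - mz_ref) <= tol
        if not mask.any() or spectrum[mask].max() <= 0:
            continue
        idx = np.flatnonzero(mask)[np.argmax(spectrum[mask])]
        observed.append(image.mz_axis[idx])
        expected.append(mz_ref)

    if len(observed) < 2:
        result = CalibrationResult(
            applied=False,
            message=f"only {len(observed)} calibration reference(s) found; "
                    "calibration skipped",
        )
        warnings.warn(result.message)
        out = image.with_axis(image.mz_axis)
        out.metadata["calibration"] = "skipped"
        return out, result

    observed = np.asarray(observed)
    expected = np.asarray(expected)
    degree = min(degree, len(observed) - 1)
    coeffs = np.polyfit(np.sqrt(observed), np.sqrt(expected), degree)
    new_axis = np.polyval(coeffs, np.sqrt(image.mz_axis)) ** 2
    mapped = np.polyval(coeffs, np.sqrt(observed)) ** 2
    residual = {
        float(e): float((m - e) / e * 1e6) for e, m in zip(expected, mapped)
    }
    passed = max(abs(v) for v in residual.values()) <= MAX_RESIDUAL_PPM
    out = image.with_axis(new_axis)
    out.metadata["calibration"] = "ok" if passed else "residual_exceeds_300ppm"
    return out, CalibrationResult(applied=True, residual_ppm=residual,
                                  passed=passed)


def extract_roi(image: SpectralImage, roi_size_um: float = 150.0) -> SpectralImage:
    """Centred square crop of ``roi_size_um`` per side.

    Pixels per side = round-half-up(roi_size_um / pixel size); the offset is
    floor((extent - side) / 2) in each direction, so a 150 um ROI on a
    128-pixel, 250 um field is a 77 x 77 crop starting at pixel (25, 25).
    """
    side = int(np.floor(roi_size_um / image.pixel_size_um + 0.5))
    if side < 1:
        raise ValueError(f"ROI of {roi_size_um} um spans no pixel")
    if side > image.width_px or side > image.height_px:
        raise ValueError(
            f"ROI of {roi_size_um} um ({side} px) exceeds the "
            f"{image.width_px}x{image.height_px} px image"
        )
    ox = (image.width_px - side) // 2
    oy = (image.height_px - side) // 2
    cropped = image.counts[oy:oy + side, ox:ox + side, :]
    out = SpectralImage(
        mz_axis=image.mz_axis.copy(),
        counts=cropped.copy(),
        pixel_size_um=image.pixel_size_um,
        polarity=image.polarity,
        metadata=dict(image.metadata),
    )
    out.metadata["roi"] = {
        "size_um": roi_size_um, "side_px": side, "offset_px": (ox, oy),
    }
    return out


def peak_windows(
    mz_values: Sequence[float],
    window_mode: str = "absolute",
    window: float = 0.05,
) -> list[tuple[float, float]]:
    """Integration windows per ion, truncated at midpoints where they overlap."""
    if window_mode not in ("absolute", "ppm"):
        raise ValueError(f"unknown window_mode {window_mode!r}")
    mz = np.asarray(mz_values, dtype=float)
    if window_mode == "absolute":
        lo, hi = mz - window, mz + window
    else:
        lo, hi = mz * (1 - window * 1e-6), mz * (1 + window * 1e-6)
    order = np.argsort(mz)
    lo_s, hi_s, mz_s = lo[order], hi[order], mz[order]
    for i in range(len(mz_s) - 1):
        if hi_s[i] > lo_s[i + 1]:
            mid = 0.5 * (mz_s[i] + mz_s[i + 1])
            hi_s[i] = min(hi_s[i], mid)
            lo_s[i + 1] = max(lo_s[i + 1], mid)
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    return [(float(lo_s[i]), float(hi_s[i])) for i in inverse]


def integrate_peaks(
    image: SpectralImage,
    ions: Sequence[IonSpec],
    window_mode: str = "absolute",
    window: float = 0.05,
) -> np.ndarray:
    """Raw integrated counts per target ion over all pixels of the image.

    Each ion's window is ``mz +- window`` (Th, or ppm in ppm mode), channel
    boundaries inclusive; neighbouring windows are truncated at the m/z
    midpoint so no channel is double-counted.
    """
    if not ions:
        return np.zeros(0)
    axis = image.mz_axis
    for ion in ions:
        if not (axis[0] - window <= ion.mz <= axis[-1] + window):
            raise ValueError(
                f"ion m/z {ion.mz} lies outside the axis range "
                f"[{axis[0]}, {axis[-1]}]"
            )
    windows = peak_windows([ion.mz for ion in ions], window_mode, window)
    channel_sums = image.counts.sum(axis=(0, 1))
    out = np.empty(len(ions))
    for i, (lo, hi) in enumerate(windows):
        mask = (axis >= lo) & (axis <= hi)
        out[i] = channel_sums[mask].sum()
    return out


def tic_normalize(raw: np.ndarray, total_ion_count: float) -> np.ndarray:
    """Divide per-ion counts by the total ion count over all channels."""
    if not total_ion_count > 0:
        raise ValueError("total ion count must be positive")
    return np.asarray(raw, dtype=float) / float(total_ion_count)


def roi_peak_intensities(
    image: SpectralImage,
    ions: Sequence[IonSpec],
    roi_size_um: float = 150.0,
    window_mode: str = "absolute",
    window: float = 0.05,
) -> np.ndarray:
    """ROI-averaged TIC-normalised intensity per target ion for one image."""
    roi = extract_roi(image, roi_size_um)
    raw = integrate_peaks(roi, ions, window_mode, window)
    return tic_normalize(raw, roi.total_ion_count())


def images_to_peak_table(
    samples: Iterable[tuple[SpectralImage, dict]],
    ions: Sequence[IonSpec],
    roi_size_um: float = 150.0,
    window_mode: str = "absolute",
    window: float = 0.05,
    calibrate: bool = True,
    calibration_refs: Sequence[tuple[float, float]] = DEFAULT_CALIBRATION_REFS,
    calibration_degree: int = 1,
) -> tuple[PeakTable, pd.DataFrame]:
    """Run calibration/ROI/integration/normalisation over a stream of images.

    ``samples`` yields (image, metadata) pairs; metadata must carry
    ``sample_id``, ``group``, ``animal`` and ``replicate``.  Returns the
    replicate-level peak table plus a per-image calibration report
    (residual ppm, pass/fail).
    """
    ions = list(ions)
    rows, meta_rows, report_rows = [], [], []
    for image, meta in samples:
        if calibrate:
            image, cal = calibrate_mass_axis(
                image, calibration_refs, calibration_degree
            )
            report_rows.append({
                "sample_id": meta["sample_id"],
                "calibration_applied": cal.applied,
                "max_abs_residual_ppm": cal.max_abs_residual_ppm,
                "passed": cal.passed,
            })
        rows.append(roi_peak_intensities(
            image, ions, roi_size_um, window_mode, window
        ))
        meta_rows.append({k: meta[k] for k in
                          ("sample_id", "group", "animal", "replicate")})
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    values = pd.DataFrame(
        np.asarray(rows), index=meta.index,
        columns=[ion.mz for ion in ions],
    )
    ion_table = pd.DataFrame(
        {
            "mz": [ion.mz for ion in ions],
            "annotation": [ion.annotation for ion in ions],
            "ion_class": [ion.ion_class for ion in ions],
        }
    ).set_index("mz")
    table = PeakTable(meta=meta, values=values, ions=ion_table)
    report = pd.DataFrame(report_rows)
    return table, report


def aggregate_replicates(table: PeakTable, policy: str = "average") -> PeakTable:
    """Collapse technical replicates to one row per animal.

    ``average`` (default) takes the arithmetic mean of each animal's
    replicate rows, so downstream statistics see animals, not
    pseudoreplicates.  ``pool`` keeps replicate rows as independent samples.
    """
    if policy == "pool":
        return table
    if policy != "average":
        raise ValueError(f"unknown replicate policy {policy!r}")
    if "animal" not in table.meta.columns:
        raise ValueError("peak table has no 'animal' column to aggregate on")
    span = table.meta.groupby("animal")["group"].nunique()
    if (span > 1).any():
        bad = span[span > 1].index[0]
        raise ValueError(f"animal {bad!r} appears in more than one group")

    joined = table.values.copy()
    joined["animal"] = table.meta["animal"]
    means = joined.groupby("animal", sort=False).mean()
    meta = (
        table.meta.reset_index()[["animal", "group"]]
        .drop_duplicates()
        .set_index("animal")
    )
    meta.index.name = "sample_id"
    means.index.name = "sample_id"
    return PeakTable(meta=meta.loc[means.index], values=means,
                     ions=table.ions.copy())
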