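"""Synthetic ToF-SIMS study generator.

Emulates the acquisition underlying the liver study: three experimental
groups (LEAN healthy controls, P1 diabetic controls, P2 metformin-treated
diabetics) with 4/8/8 animals, three technical replicates per animal, each
replicate a 128 x 128 pixel negative-ion image over a 250 x 250 um field
with spectra on an m/z 0-911 axis.

The signal model is counting-statistics driven: every target ion's count in
a pixel is Poisson with mean

    group_mean * pixel_TIC_budget * texture_multiplier,

where ``group_mean`` is the ion's TIC-normalised mean relative intensity for
the animal's group, the pixel TIC budget fluctuates between replicates
(log-normal, CV ``tic_cv``) and across the field through a smooth
multiplicative texture (liver lobular microstructure is homogeneous, so the
texture is a Gaussian-filtered random field, not compartments).  A broadband
background of pseudo-ions fills the TIC fraction not assigned to target
ions, so normalisation to total ion counts is non-degenerate.  Animal-level
biological variability is a log-normal per-ion scale factor applied before
Poisson sampling, making between-animal variance exceed between-replicate
variance.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from simscape.image import SpectralImage

ION_CLASSES = ("lipid", "amino_acid", "other")

#: Reference negative ions used for internal mass calibration:
#: H-, C-, CH-, C2-, C3-.
CALIBRATION_REFERENCE_MZ = (1.0078, 12.0000, 13.0078, 24.0000, 36.0000)

#: Upper end of the acquired mass range (Th).
MZ_MAX = 911.0

_N_BACKGROUND = 50


@dataclass
class IonSpec:
    """A target ion: position, annotation, class and per-group mean.

    ``group_mean`` maps group name to the TIC-normalised mean relative
    intensity (dimensionless fraction of the total ion count).
    """

    mz: float
    annotation: str
    ion_class: str
    group_mean: dict[str, float]

    def __post_init__(self) -> None:
        if not 0 < self.mz <= MZ_MAX:
            raise ValueError(f"ion m/z {self.mz} outside (0, {MZ_MAX}]")
        if self.ion_class not in ION_CLASSES:
            raise ValueError(
                f"ion_class {self.ion_class!r} not one of {ION_CLASSES}"
            )
        for group, mean in self.group_mean.items():
            if not 0 <= mean < 1:
                raise ValueError(
                    f"group mean {mean} for {group!r} at m/z {self.mz} "
                    "outside [0, 1)"
                )


@dataclass
class StudyDesign:
    """Group/animal/replicate structure and geometry of a study."""

    groups: tuple[str, ...] = ("LEAN", "P1", "P2")
    animals_per_group: dict[str, int] = field(
        default_factory=lambda: {"LEAN": 4, "P1": 8, "P2": 8}
    )
    technical_replicates: int = 3
    image_width_px: int = 128
    image_height_px: int = 128
    field_of_view_um: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group names must be unique")
        for g in self.groups:
            if self.animals_per_group.get(g, 0) < 1:
                raise ValueError(f"group {g!r} needs at least one animal")
        if self.technical_replicates < 1:
            raise ValueError("technical_replicates must be >= 1")
        if self.image_width_px < 1 or self.image_height_px < 1:
            raise ValueError("image dimensions must be >= 1 pixel")
        if not self.field_of_view_um > 0:
            raise ValueError("field_of_view_um must be positive")

    @property
    def pixel_size_um(self) -> float:
        return self.field_of_view_um / self.image_width_px

    @property
    def n_animals(self) -> int:
        return sum(self.animals_per_group[g] for g in self.groups)

    @property
    def n_images(self) -> int:
        return self.n_animals * self.technical_replicates


#: Default detected-ion dose in counts per um^2.  At the static-SIMS fluence
#: limit (1e12 primary ions / cm^2 = 1e4 / um^2) a useful yield times
#: transmission of ~0.13 gives ~1300 detected secondaries per um^2 — 5000
#: counts in one 2 um pixel of the default 128-px / 250-um geometry.
DEFAULT_TIC_PER_UM2 = 1310.72


@dataclass
class NoiseModel:
    """Noise and nuisance parameters of the generator.

    ``tic_per_pixel_mean`` is the expected total count per pixel.  Left at
    None it is derived from the primary-ion dose as
    ``DEFAULT_TIC_PER_UM2 * pixel_area``, so coarsening the pixel grid over
    the same field conserves total counts (the counting statistics of an
    ROI then do not depend on the raster resolution).
    """

    tic_per_pixel_mean: float | None = None
    tic_cv: float = 0.05
    texture_length_um: float = 30.0
    texture_cv: float = 0.15
    drift_ppm: float = 0.0
    counting_noise: bool = True  # False replaces Poisson draws by their mean

    def __post_init__(self) -> None:
        for name in ("tic_per_pixel_mean", "tic_cv", "texture_length_um",
                     "texture_cv"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0")

    def tic_budget(self, pixel_size_um: float) -> float:
        """Expected counts per pixel for a given pixel edge length."""
        if self.tic_per_pixel_mean is not None:
            return self.tic_per_pixel_mean
        return DEFAULT_TIC_PER_UM2 * pixel_size_um**2


def load_reference_ions() -> list[IonSpec]:
    """Load the bundled 26-ion negative-mode reference panel.

    The panel holds the 10 statistically significant lipid-related ions and
    16 amino-acid-related ions with their published TIC-normalised group
    means for LEAN, P1 and P2.  Note the panel follows its source tables
    verbatim, including the m/z 115.011 "Aspartic acid" entry carried in the
    lipid family.
    """
    table = reference_table()
    ions = []
    for mz, row in table.iterrows():
        ions.append(
            IonSpec(
                mz=float(mz),
                annotation=str(row["annotation"]),
                ion_class=str(row["ion_class"]),
                group_mean={
                    "LEAN": float(row["mean_LEAN"]),
                    "P1": float(row["mean_P1"]),
                    "P2": float(row["mean_P2"]),
                },
            )
        )
    return ions


def reference_table() -> pd.DataFrame:
    """The bundled reference panel as a DataFrame indexed by m/z.

    Includes the published per-ion log2 fold changes versus P1, trend
    labels and q-values alongside the group means.
    """
    resource = importlib.resources.files("simscape.data") / "reference_ions.csv"
    with importlib.resources.as_file(resource) as path:
        table = pd.read_csv(path)
    required = {"mz", "annotation", "ion_class", "mean_LEAN", "mean_P1",
                "mean_P2", "log2fc_lean_p1", "log2fc_p2_p1", "trend", "q"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"reference ion table is missing columns {sorted(missing)}")
    if table[list(required - {"annotation", "trend", "ion_class"})].isna().any().any():
        bad = table.loc[table.isna().any(axis=1), "mz"].tolist()
        raise ValueError(f"reference ion table has incomplete rows at m/z {bad}")
    n_lipid = int((table["ion_class"] == "lipid").sum())
    n_amino = int((table["ion_class"] == "amino_acid").sum())
    if n_lipid != 10 or n_amino != 16:
        raise ValueError(
            f"reference ion table must hold 10 lipid + 16 amino-acid ions, "
            f"found {n_lipid} + {n_amino}"
        )
    return table.set_index("mz")


def _background_channels(
    ions: Iterable[IonSpec],
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and relative weights of the broadband background.

    50 pseudo-ions: the five calibration references (always present and
    intense, as in real negative-ion spectra) plus 45 positions spread over
    the mass range, nudged away from any target ion so integration windows
    never overlap.  Weights fall off exponentially with mass, mimicking the
    declining secondary-ion yield, and are normalised to sum to one.
    """
    targets = np.array(sorted(ion.mz for ion in ions), dtype=float)
    positions = list(CALIBRATION_REFERENCE_MZ)
    spread = np.linspace(45.0, 900.0, _N_BACKGROUND - len(positions))
    for mz in spread:
        while targets.size and np.min(np.abs(targets - mz)) < 0.5:
            mz += 0.53
        positions.append(round(mz, 4))
    positions = np.array(positions, dtype=float)
    weights = np.exp(-positions / 200.0)
    weights[: len(CALIBRATION_REFERENCE_MZ)] *= 5.0  # H-/C-/CH-/C2-/C3- dominate
    return positions, weights / weights.sum()


def _texture_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    length_um: float,
    cv: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Smooth multiplicative random field with mean 1 and amplitude ``cv``."""
    if cv == 0:
        return np.ones(shape)
    white = rng.standard_normal(shape)
    sigma_px = max(length_um / pixel_size_um, 1e-9)
    smooth = gaussian_filter(white, sigma=sigma_px, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.ones(shape)
    fieldv = 1.0 + cv * (smooth - smooth.mean()) / sd
    return np.clip(fieldv, 0.05, None)


def _lognormal_scale(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Log-normal draws with mean exactly 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(() if size is None else size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_image(
    ions: list[IonSpec],
    group: str,
    noise: NoiseModel,
    design: StudyDesign,
    seed: int,
    animal_scale: np.ndarray | None = None,
) -> SpectralImage:
    """Generate one replicate image for one animal of ``group``.

    The channel axis is sparse: one channel per target ion plus 50
    background pseudo-ion channels (including the five calibration
    references).  ``animal_scale`` optionally multiplies each target ion's
    group mean (per-animal biological variability); ``generate_study``
    supplies it.

    Deterministic under a fixed ``seed``.  If ``noise.drift_ppm`` is
    non-zero the returned m/z axis is shifted multiplicatively by that many
    ppm, emulating an uncalibrated time-of-flight axis.
    """
    for ion in ions:
        if group not in ion.group_mean:
            raise KeyError(
                f"group {group!r} missing from ion m/z {ion.mz} group_mean"
            )
    tic_mean = noise.tic_budget(design.pixel_size_um)
    if not tic_mean > 0:
        raise ValueError("TIC budget per pixel must be positive")

    rng = np.random.default_rng(seed)
    order = np.argsort([ion.mz for ion in ions])
    ions_sorted = [ions[i] for i in order]
    target_mz = np.array([ion.mz for ion in ions_sorted])
    target_frac = np.array([ion.group_mean[group] for ion in ions_sorted])
    if animal_scale is not None:
        scale = np.asarray(animal_scale, dtype=float)[order]
        target_frac = target_frac * scale

    bg_mz, bg_weight = _background_channels(ions_sorted)
    bg_total = 1.0 - target_frac.sum()
    if bg_total < 0:
        raise ValueError(
            "target ion fractions exceed the TIC budget (sum > 1); "
            "negative background remainder"
        )

    mz_axis = np.concatenate([target_mz, bg_mz])
    frac = np.concatenate([target_frac, bg_weight * bg_total])
    sort_idx = np.argsort(mz_axis)
    mz_axis = mz_axis[sort_idx]
    frac = frac[sort_idx]

    shape = (design.image_height_px, design.image_width_px)
    rep_scale = float(_lognormal_scale(rng, noise.tic_cv, None))
    texture = _texture_field(
        rng, shape, noise.texture_length_um, noise.texture_cv,
        design.pixel_size_um,
    )
    tic_budget = tic_mean * rep_scale * texture  # (H, W)
    mean = tic_budget[:, :, None] * frac[None, None, :]
    if noise.counting_noise:
        counts = rng.poisson(mean).astype(float)
    else:
        counts = mean

    if noise.drift_ppm != 0:
        mz_axis = mz_axis * (1.0 + noise.drift_ppm * 1e-6)

    return SpectralImage(
        mz_axis=mz_axis,
        counts=counts,
        pixel_size_um=design.pixel_size_um,
        polarity="negative",
        metadata={"group": group, "seed": int(seed),
                  "drift_ppm": float(noise.drift_ppm)},
    )


def iter_study(
    design: StudyDesign,
    ions: list[IonSpec],
    noise: NoiseModel | None = None,
    animal_cv: float = 0.10,
) -> Iterator[tuple[SpectralImage, dict]]:
    """Lazily yield one (image, metadata row) pair per (animal, replicate).

    Metadata rows carry ``sample_id``, ``group``, ``animal``, ``replicate``
    and the per-image ``seed``.  All randomness derives from ``design.seed``
    so a study is bit-identical across runs.
    """
    if noise is None:
        noise = NoiseModel()
    master = np.random.default_rng(design.seed)
    for group in design.groups:
        for a in range(1, design.animals_per_group[group] + 1):
            animal_id = f"{group}_a{a:02d}"
            scale = _lognormal_scale(master, animal_cv, len(ions))
            for r in range(1, design.technical_replicates + 1):
                child_seed = int(master.integers(0, 2**31))
                image = generate_image(
                    ions, group, noise, design, child_seed,
                    animal_scale=scale,
                )
                meta = {
                    "sample_id": f"{animal_id}_r{r}",
                    "group": group,
                    "animal": animal_id,
                    "replicate": r,
                    "seed": child_seed,
                }
                yield image, meta


def generate_study(
    design: StudyDesign,
    ions: list[IonSpec],
    noise: NoiseModel | None = None,
    animal_cv: float = 0.10,
) -> tuple[list[SpectralImage], pd.DataFrame]:
    """Generate a full study in memory.

    Returns one image per (animal, replicate) — 60 for the default design —
    plus the sample metadata table.  For large designs prefer
    :func:`iter_study`, which streams images instead of holding them all.
    """
    images, rows = [], []
    for image, meta in iter_study(design, ions, noise, animal_cv):
        images.append(image)
        rows.append(meta)
    return images, pd.DataFrame(rows)


def write_study(
    out_dir,
    design: StudyDesign,
    ions: list[IonSpec],
    noise: NoiseModel | None = None,
    animal_cv: float = 0.10,
) -> pd.DataFrame:
    """Write a study to disk as imzML files plus a sample-metadata CSV.

    Streams one image at a time.  Returns the metadata table, which is also
    written to ``<out_dir>/samples.csv`` with a ``file`` column pointing at
    each imzML file.
    """
    from pathlib import Path

    from simscape.io import write_imzml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for image, meta in iter_study(design, ions, noise, animal_cv):
        fname = f"{meta['sample_id']}.imzML"
        write_imzml(image, out / fname)
        meta = dict(meta, file=fname)
        rows.append(meta)
    table = pd.DataFrame(rows)
    table.to_csv(out / "samples.csv", index=False)
    return table
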