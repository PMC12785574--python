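"""Report surfaces: volcano tables, Z-scored clustering, ion maps, boxplots.

Every figure has a data-behind-the-figure table that is exported losslessly
as CSV; PNG renderings are a thin matplotlib layer on top.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from simscape.image import SpectralImage
from simscape.io import PeakTable
from simscape.stats import DifferentialResult

CONTRASTS = {
    "LEAN_vs_P1": ("LEAN", "P1"),
    "P2_vs_P1": ("P2", "P1"),
}


def volcano_data(
    results: list[DifferentialResult],
    contrast: str,
    fc_threshold: float = 0.6,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Volcano-plot table for one pairwise contrast.

    ``log2fc`` is the contrast's fold change versus P1 and the p-value is
    the Tukey pairwise p for that contrast (a per-contrast volcano needs a
    per-contrast p, not the omnibus ANOVA p).  An ion is flagged when
    |log2FC| strictly exceeds ``fc_threshold`` and p < ``p_threshold``.
    """
    if not results:
        raise ValueError("no differential results supplied")
    if contrast not in CONTRASTS:
        raise ValueError(
            f"unknown contrast {contrast!r}; expected one of {sorted(CONTRASTS)}"
        )
    pair = CONTRASTS[contrast]
    rows = []
    for r in results:
        fc = r.log2fc_lean_p1 if contrast == "LEAN_vs_P1" else r.log2fc_p2_p1
        p = r.tukey_p.get(pair)
        if p is None:
            p = r.tukey_p.get((pair[1], pair[0]), float("nan"))
        flagged = (
            np.isfinite(fc) and abs(fc) > fc_threshold and p < p_threshold
        )
        rows.append({
            "mz": r.mz,
            "annotation": r.annotation,
            "log2fc": fc,
            "p": p,
            "neg_log10_p": -np.log10(p) if p > 0 else np.inf,
            "flagged": bool(flagged),
        })
    return pd.DataFrame(rows)


def zscore_cluster(
    table: PeakTable,
) -> tuple[list[str], list[float], np.ndarray, np.ndarray, pd.DataFrame]:
    """Z-score per ion across samples and cluster both ways.

    Each ion is standardised to mean 0, sd 1 across samples; ions with zero
    variance are dropped with a warning.  Agglomerative clustering uses
    Euclidean distance with Ward linkage; scipy's leaf ordering is
    deterministic for a given linkage (ties broken by observation index).

    Returns (sample order, ion order, sample linkage, ion linkage,
    Z matrix as DataFrame samples x ions).
    """
    values = table.values
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("clustering needs at least two samples and two ions")
    sd = values.std(axis=0, ddof=0)
    dropped = [float(c) for c in values.columns[sd == 0]]
    if dropped:
        warnings.warn(f"dropping zero-variance ions at m/z {dropped}")
        values = values.loc[:, sd > 0]
    z = (values - values.mean(axis=0)) / values.std(axis=0, ddof=0)
    sample_linkage = linkage(z.to_numpy(), method="ward")
    ion_linkage = linkage(z.to_numpy().T, method="ward")
    sample_order = [z.index[i] for i in leaves_list(sample_linkage)]
    ion_order = [float(z.columns[i]) for i in leaves_list(ion_linkage)]
    return sample_order, ion_order, sample_linkage, ion_linkage, z


def top_k_by_q(
    results: list[DifferentialResult], k: int = 40
) -> list[float]:
    """The k most significant ions (ascending q, m/z as tie-break)."""
    ranked = sorted(results, key=lambda r: (r.q, r.mz))
    return [r.mz for r in ranked[:k]]


def ion_map(
    image: SpectralImage,
    mz: float,
    window: float = 0.05,
    scale: str = "fixed",
    fixed_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Per-pixel TIC-normalised intensity raster for one ion.

    Integrated counts within ``mz +- window`` divided by the pixel's total
    ion count (pixels with zero TIC map to 0).  With ``scale='fixed'`` the
    returned colour range is ``fixed_range`` (shared across all images of
    the same ion); with ``'auto'`` it is the raster's own min/max.
    """
    mask = np.abs(image.mz_axis - mz) <= window
    if not mask.any():
        raise ValueError(
            f"integration window {mz} +- {window} contains no channel"
        )
    ion_counts = image.counts[:, :, mask].sum(axis=2)
    tic = image.counts.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        raster = np.where(tic > 0, ion_counts / np.where(tic > 0, tic, 1), 0.0)
    if scale == "fixed":
        if fixed_range is None:
            raise ValueError("scale='fixed' requires fixed_range")
        vmin, vmax = fixed_range
    elif scale == "auto":
        vmin, vmax = float(raster.min()), float(raster.max())
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return raster, (float(vmin), float(vmax))


def boxplot_summaries(
    table: PeakTable, ions: Sequence[float]
) -> pd.DataFrame:
    """Tukey five-number summaries per ion and group.

    Median, quartiles, whiskers at the most extreme points within 1.5 x IQR
    of the box, and the individual data points (points beyond the whiskers
    are the outliers of a standard box plot).
    """
    rows = []
    for mz in ions:
        mz = float(mz)
        if mz not in [float(c) for c in table.values.columns]:
            raise ValueError(f"ion m/z {mz} absent from the peak table")
        for group in pd.unique(table.meta["group"]):
            vals = table.values[mz][table.meta["group"] == group].to_numpy()
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            in_lo = vals[vals >= q1 - 1.5 * iqr]
            in_hi = vals[vals <= q3 + 1.5 * iqr]
            rows.append({
                "mz": mz,
                "group": group,
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_lo": in_lo.min() if in_lo.size else q1,
                "whisker_hi": in_hi.max() if in_hi.size else q3,
                "n": vals.size,
                "points": ";".join(f"{v:.12g}" for v in vals),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# matplotlib renderers (thin layer; the CSV exports above are the artefacts)


def render_volcano(volcano: pd.DataFrame, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = np.where(volcano["flagged"], "crimson", "grey")
    y = volcano["neg_log10_p"].replace(np.inf, volcano["neg_log10_p"]
                                       .replace(np.inf, np.nan).max() * 1.1)
    ax.scatter(volcano["log2fc"], y, c=colors, s=18)
    for _, row in volcano[volcano["flagged"]].iterrows():
        ax.annotate(f"{row['mz']:g}", (row["log2fc"], row["neg_log10_p"]),
                    fontsize=7)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_heatmap(
    z: pd.DataFrame, sample_order, ion_order, path, title: str = ""
) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = z.loc[sample_order, ion_order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(ordered.to_numpy().T, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(sample_order)))
    ax.set_xticklabels(sample_order, rotation=90, fontsize=5)
    ax.set_yticks(range(len(ion_order)))
    ax.set_yticklabels([f"{m:g}" for m in ion_order], fontsize=5)
    fig.colorbar(im, ax=ax, label="Z score")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_ion_map(raster: np.ndarray, vrange, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(raster, vmin=vrange[0], vmax=vrange[1], cmap="inferno")
    fig.colorbar(im, ax=ax, label="TIC-normalised intensity")
    ax.set_title(title)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_boxplots(summaries: pd.DataFrame, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ions = summaries["mz"].unique()
    fig, axes = plt.subplots(1, len(ions), figsize=(2.4 * len(ions), 3.2),
                             squeeze=False)
    for ax, mz in zip(axes[0], ions):
        sub = summaries[summaries["mz"] == mz]
        data = [np.array([float(v) for v in row["points"].split(";")])
                for _, row in sub.iterrows()]
        ax.boxplot(data, tick_labels=list(sub["group"]))
        for i, vals in enumerate(data, start=1):
            ax.plot(np.full(vals.size, i), vals, "k.", ms=3, alpha=0.6)
        ax.set_title(f"m/z {mz:g}", fontsize=8)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
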