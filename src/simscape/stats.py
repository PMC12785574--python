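"""Per-ion three-group inference.

For every ion in a peak table of animal-level TIC-normalised intensities:
one-way ANOVA across LEAN/P1/P2, Tukey-Kramer pairwise contrasts,
Benjamini-Hochberg FDR correction (within ion-class family by default),
log2 fold changes against the diabetic control P1, a sign-based trend
taxonomy (Up / Down / Mixed versus P1), and the recovery index

    100 * (I_P2 - I_P1) / (I_LEAN - I_P1),

the percentage of the disease-control gap closed by treatment: 0% means no
change relative to P1, 100% full convergence to the LEAN level; overshoot
is reported, never clipped.  Normality (Shapiro-Wilk) and variance
homogeneity (Levene) are reported as diagnostics and never gate the ANOVA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from simscape.io import PeakTable

#: Denominator below this absolute value makes the recovery index undefined.
RECOVERY_DEGENERACY_THRESHOLD = 1e-12

_PAIRS = (("LEAN", "P1"), ("P2", "P1"), ("LEAN", "P2"))


@dataclass
class DifferentialResult:
    """Per-ion differential statistics across the three groups."""

    mz: float
    annotation: str
    ion_class: str
    mean: dict[str, float]
    sem: dict[str, float]
    f_statistic: float
    p_anova: float
    q: float
    tukey_p: dict[tuple[str, str], float]
    log2fc_lean_p1: float
    log2fc_p2_p1: float
    trend: str | None
    recovery_pct: float
    shapiro_p: dict[str, float]
    levene_p: float
    significant: bool
    flags: tuple[str, ...] = ()


def one_way_anova(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    Between/within F with (k-1, N-k) degrees of freedom via
    ``scipy.stats.f_oneway``.  Degenerate inputs are resolved by
    convention: all observations identical -> (F=0, p=1) with a warning;
    zero within-group variance with distinct means -> (F=inf, p=0).
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for name, arr in zip(groups, arrays):
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than two observations")
    within_ss = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    means = np.array([a.mean() for a in arrays])
    if within_ss == 0:
        if np.ptp(means) == 0:
            warnings.warn("all observations identical; ANOVA p set to 1")
            return 0.0, 1.0
        return math.inf, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = scipy.stats.f_oneway(*arrays)
    return float(f_stat), float(p)


def tukey_hsd(
    groups: dict[str, np.ndarray],
    pair: tuple[str, str] | None = None,
):
    """Tukey-Kramer studentized-range pairwise p-values (unequal n allowed).

    Returns the adjusted p for ``pair``, or a dict over all pairs when
    ``pair`` is None.  Degenerate zero-variance inputs follow the ANOVA
    conventions (identical groups -> p=1; separated constant groups -> p=0).
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for name, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than two observations")
    within_ss = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    out: dict[tuple[str, str], float] = {}
    if within_ss == 0:
        for i, gi in enumerate(names):
            for gj in names[i + 1:]:
                same = arrays[i].mean() == np.asarray(groups[gj]).mean()
                out[(gi, gj)] = 1.0 if same else 0.0
    else:
        res = scipy.stats.tukey_hsd(*arrays)
        for i, gi in enumerate(names):
            for j, gj in enumerate(names):
                if j > i:
                    out[(gi, gj)] = float(res.pvalue[i, j])
    if pair is None:
        return out
    key = tuple(pair)
    if key in out:
        return out[key]
    if (key[1], key[0]) in out:
        return out[(key[1], key[0])]
    raise KeyError(f"unknown group pair {pair!r}")


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_(j>=i) p_(j) * m / j`` over the ascending order, capped
    at 1 and mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def log2_fold_change(mean_a: float, mean_b: float) -> float:
    """log2(mean_a / mean_b) of two TIC-normalised group means.

    Returns NaN (missing, flagged upstream) when either mean is not
    strictly positive.
    """
    if not (mean_a > 0 and mean_b > 0):
        return float("nan")
    return math.log2(mean_a / mean_b)


def classify_trend(
    log2fc_lean_p1: float, log2fc_p2_p1: float
) -> str | None:
    """Sign-based trend versus the diabetic control P1.

    Both contrasts positive -> ``Up`` (depleted in disease, restored by
    treatment); both negative -> ``Down`` (elevated in disease, lowered by
    treatment); opposite signs or an exact zero -> ``Mixed`` (divergent or
    bidirectional).  Returns None when either input is missing.
    """
    if any(x is None or math.isnan(x) for x in (log2fc_lean_p1, log2fc_p2_p1)):
        return None
    if log2fc_lean_p1 > 0 and log2fc_p2_p1 > 0:
        return "Up"
    if log2fc_lean_p1 < 0 and log2fc_p2_p1 < 0:
        return "Down"
    return "Mixed"


def recovery_index(i_lean: float, i_p1: float, i_p2: float) -> float:
    """Percent of the LEAN-P1 gap recovered in the treated group P2.

    ``100 * (I_P2 - I_P1) / (I_LEAN - I_P1)``; values outside [0, 100]
    (overshoot) are reported as-is.  A denominator below the degeneracy
    threshold yields NaN.
    """
    denom = i_lean - i_p1
    if abs(denom) <= RECOVERY_DEGENERACY_THRESHOLD:
        return float("nan")
    return 100.0 * (i_p2 - i_p1) / denom


def class_contribution(table: PeakTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative contribution of amino-acid vs lipid ions, per sample and group.

    Per sample: amino% = 100 * sum(amino-class intensities) /
    sum(amino + lipid intensities); lipid% analogously.  Ions of class
    ``other`` are excluded from the denominator.  The group summary is
    mean +- SEM over samples.
    """
    if table.ions.empty:
        raise ValueError("peak table carries no ion class annotations")
    classes = table.ions["ion_class"]
    amino_mz = [m for m in table.values.columns if classes.get(float(m)) == "amino_acid"]
    lipid_mz = [m for m in table.values.columns if classes.get(float(m)) == "lipid"]
    if not amino_mz or not lipid_mz:
        raise ValueError(
            "class contribution needs at least one amino_acid and one lipid ion"
        )
    amino_sum = table.values[amino_mz].sum(axis=1)
    lipid_sum = table.values[lipid_mz].sum(axis=1)
    total = amino_sum + lipid_sum
    per_sample = pd.DataFrame({
        "group": table.meta["group"],
        "amino_pct": 100.0 * amino_sum / total,
        "lipid_pct": 100.0 * lipid_sum / total,
    })
    grouped = per_sample.groupby("group", sort=False)
    summary = grouped.agg(
        amino_pct_mean=("amino_pct", "mean"),
        amino_pct_sem=("amino_pct", "sem"),
        lipid_pct_mean=("lipid_pct", "mean"),
        lipid_pct_sem=("lipid_pct", "sem"),
        n=("amino_pct", "size"),
    )
    return per_sample, summary


def assumption_checks(
    groups: dict[str, np.ndarray],
) -> tuple[dict[str, float], float]:
    """Shapiro-Wilk normality p per group and a Levene homogeneity p.

    Groups with fewer than three observations get NaN for normality.
    Diagnostics only — they never gate the ANOVA.
    """
    shapiro_p = {}
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        if values.size < 3 or np.ptp(values) == 0:
            shapiro_p[name] = float("nan")
            continue
        shapiro_p[name] = float(scipy.stats.shapiro(values).pvalue)
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if all(np.ptp(a) == 0 for a in arrays):
        levene_p = float("nan")
    else:
        levene_p = float(scipy.stats.levene(*arrays, center="mean").pvalue)
    return shapiro_p, levene_p


def run_differential(
    table: PeakTable,
    alpha: float = 0.05,
    control: str = "LEAN",
    baseline: str = "P1",
    treated: str = "P2",
    family_mode: str = "per_class",
) -> list[DifferentialResult]:
    """Full per-ion differential analysis of an animal-level peak table.

    ``family_mode='per_class'`` applies the Benjamini-Hochberg correction
    separately within each ion-class family (lipids and amino acids form
    distinct panels); ``'pooled'`` corrects all ions as one family.
    """
    if family_mode not in ("per_class", "pooled"):
        raise ValueError(f"unknown family_mode {family_mode!r}")
    for g in (control, baseline, treated):
        n = int((table.meta["group"] == g).sum())
        if n < 2:
            raise ValueError(f"group {g!r} has {n} sample(s); need >= 2")

    results: list[DifferentialResult] = []
    for mz in table.values.columns:
        mz = float(mz)
        groups = {
            g: table.values[mz][table.meta["group"] == g].to_numpy()
            for g in (control, baseline, treated)
        }
        flags: list[str] = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p_anova = one_way_anova(groups)
            tukey = tukey_hsd(groups)
            shapiro_p, levene_p = assumption_checks(groups)
        if not math.isfinite(f_stat):
            flags.append("degenerate_zero_within_variance")
        means = {g: float(v.mean()) for g, v in groups.items()}
        sems = {
            g: float(v.std(ddof=1) / math.sqrt(v.size))
            for g, v in groups.items()
        }
        fc_lean = log2_fold_change(means[control], means[baseline])
        fc_treated = log2_fold_change(means[treated], means[baseline])
        if math.isnan(fc_lean) or math.isnan(fc_treated):
            flags.append("nonpositive_group_mean")
        trend = classify_trend(fc_lean, fc_treated)
        rec = recovery_index(means[control], means[baseline], means[treated])
        if math.isnan(rec) and "nonpositive_group_mean" not in flags:
            flags.append("degenerate_recovery_denominator")
        results.append(DifferentialResult(
            mz=mz,
            annotation=str(table.ions.loc[mz, "annotation"])
            if (not table.ions.empty and mz in table.ions.index) else "",
            ion_class=table.ion_class_of(mz),
            mean=means,
            sem=sems,
            f_statistic=f_stat,
            p_anova=p_anova,
            q=float("nan"),
            tukey_p={
                pair: tukey.get(pair, tukey.get(pair[::-1]))
                for pair in ((control, baseline), (treated, baseline),
                             (control, treated))
            },
            log2fc_lean_p1=fc_lean,
            log2fc_p2_p1=fc_treated,
            trend=trend,
            recovery_pct=rec,
            shapiro_p=shapiro_p,
            levene_p=levene_p,
            significant=False,
            flags=tuple(flags),
        ))

    if family_mode == "per_class":
        families: dict[str, list[int]] = {}
        for i, r in enumerate(results):
            families.setdefault(r.ion_class, []).append(i)
    else:
        families = {"all": list(range(len(results)))}
    for indices in families.values():
        q = benjamini_hochberg(np.array([results[i].p_anova for i in indices]))
        for i, qi in zip(indices, q):
            results[i].q = float(qi)
            results[i].significant = bool(qi < alpha)
    return results


def results_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Flatten differential results to a table mirroring the published layout.

    Columns: m/z, annotation, ion class, trend, per-group means and SEMs,
    the two log2 fold changes versus P1, recovery index, F, p, q, pairwise
    Tukey p-values and assumption diagnostics.
    """
    rows = []
    for r in results:
        row = {
            "mz": r.mz,
            "annotation": r.annotation,
            "ion_class": r.ion_class,
            "trend": r.trend,
        }
        for g, m in r.mean.items():
            row[f"mean_{g}"] = m
        for g, s in r.sem.items():
            row[f"sem_{g}"] = s
        row.update({
            "log2fc_lean_p1": r.log2fc_lean_p1,
            "log2fc_p2_p1": r.log2fc_p2_p1,
            "recovery_pct": r.recovery_pct,
            "F": r.f_statistic,
            "p_anova": r.p_anova,
            "q": r.q,
            "significant": r.significant,
        })
        for (ga, gb), p in r.tukey_p.items():
            row[f"tukey_p_{ga}_{gb}"] = p
        for g, p in r.shapiro_p.items():
            row[f"shapiro_p_{g}"] = p
        row["levene_p"] = r.levene_p
        row["flags"] = ";".join(r.flags)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("q", kind="stable").reset_index(drop=True)


def frame_to_results(frame: pd.DataFrame) -> list[DifferentialResult]:
    """Rebuild :class:`DifferentialResult` objects from a results table.

    Inverse of :func:`results_to_frame` (used when the report stage is fed
    a results CSV instead of in-memory results).
    """
    groups = [c[len("mean_"):] for c in frame.columns if c.startswith("mean_")]
    results = []
    for _, row in frame.iterrows():
        tukey = {}
        for col in frame.columns:
            if col.startswith("tukey_p_"):
                ga, gb = col[len("tukey_p_"):].split("_", 1)
                tukey[(ga, gb)] = float(row[col])
        results.append(DifferentialResult(
            mz=float(row["mz"]),
            annotation=str(row.get("annotation", "")),
            ion_class=str(row.get("ion_class", "other")),
            mean={g: float(row[f"mean_{g}"]) for g in groups},
            sem={g: float(row.get(f"sem_{g}", float("nan"))) for g in groups},
            f_statistic=float(row["F"]),
            p_anova=float(row["p_anova"]),
            q=float(row["q"]),
            tukey_p=tukey,
            log2fc_lean_p1=float(row["log2fc_lean_p1"]),
            log2fc_p2_p1=float(row["log2fc_p2_p1"]),
            trend=None if pd.isna(row["trend"]) else str(row["trend"]),
            recovery_pct=float(row["recovery_pct"]),
            shapiro_p={g: float(row.get(f"shapiro_p_{g}", float("nan")))
                       for g in groups},
            levene_p=float(row.get("levene_p", float("nan"))),
            significant=bool(row["significant"]),
            flags=tuple(str(row.get("flags", "")).split(";"))
            if str(row.get("flags", "")) not in ("", "nan") else (),
        ))
    return results
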