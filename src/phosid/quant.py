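"""Site tables, enrichment accounting, and condition comparison.

Aggregates accepted, localized PSMs into probe-site records, summarises
enrichment efficiency as per-class shares of MS1-assigned intensity, and runs
the label-free comparison between two conditions: replicate-presence
filtering, log2 transform, normality diagnostic, downshifted Gaussian
imputation of missing values, per-site Student's t-test with fold-change and
significance classes, and intensity/iBAQ prioritization of sites.

Conventions: a site is kept in the tryptic regime when seen in at least
``min_replicates`` replicates of at least one condition (the 2-of-3 rule by
default); in the pepsin regime when it accumulates at least
``pepsin_min_psms`` PSMs.  Missing log2 values are imputed per column from
``Normal(mean - 1.8*SD, (0.3*SD)^2)``, the conventional downshift used for
left-censored label-free data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QuantParams",
    "enrichment_summary",
    "build_site_table",
    "normality_report",
    "impute_missing",
    "compare_conditions",
    "ibaq_prioritize",
    "volcano_plot",
]


@dataclass(frozen=True)
class QuantParams:
    min_replicates: int = 2
    downshift_sd: float = 1.8
    impute_width_sd: float = 0.3
    fc_threshold: float = 2.0
    alpha: float = 0.05
    pepsin_min_psms: int = 2
    equal_variance: bool = True       # Student's t; False gives Welch
    bh_correction: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")


def enrichment_summary(psms: pd.DataFrame) -> pd.DataFrame:
    """Per-run class shares of total MS1-assigned intensity.

    ``psms`` needs columns ``run``, ``class`` and ``intensity``.  Fractions
    sum to one within each run; a run with zero total intensity is an error.
    """
    required = {"run", "class", "intensity"}
    if not required <= set(psms.columns):
        raise ValueError(f"missing columns: {sorted(required - set(psms.columns))}")
    out = []
    for run, group in psms.groupby("run", sort=False):
        total = group["intensity"].sum()
        if total <= 0:
            raise ValueError(f"run {run!r} has zero total intensity")
        shares = group.groupby("class")["intensity"].sum() / total
        for cls, fraction in shares.items():
            out.append({"run": run, "class": cls,
                        "fraction": float(fraction)})
    return pd.DataFrame(out)


def build_site_table(
    sites: pd.DataFrame,
    params: QuantParams = QuantParams(),
    protease_mode: str = "tryptic",
) -> pd.DataFrame:
    """Filter localized site evidence into the final site table.

    ``sites`` has one row per localized-PSM contribution with columns
    ``protein``, ``position``, ``condition``, ``replicate``, ``intensity``
    (and ``n_psms``, defaulting to one per row).  Site intensity per
    (condition, replicate) is the sum of its peptide intensities.  Tryptic
    regime keeps a site present in >= ``min_replicates`` replicates of at
    least one condition; pepsin regime keeps a site with >=
    ``pepsin_min_psms`` PSMs in total.  The filter is idempotent.
    """
    if protease_mode not in ("tryptic", "pepsin"):
        raise ValueError(f"unknown protease mode {protease_mode!r}")
    df = sites.copy()
    if "n_psms" not in df.columns:
        df["n_psms"] = 1
    agg = (df.groupby(["protein", "position", "condition", "replicate"])
             .agg(intensity=("intensity", "sum"), n_psms=("n_psms", "sum"))
             .reset_index())
    keep: list[tuple] = []
    for (protein, position), group in agg.groupby(["protein", "position"]):
        if protease_mode == "tryptic":
            present = group[group["intensity"] > 0]
            by_condition = present.groupby("condition")["replicate"].nunique()
            if (by_condition >= params.min_replicates).any():
                keep.append((protein, position))
        else:
            if group["n_psms"].sum() >= params.pepsin_min_psms:
                keep.append((protein, position))
    mask = agg.set_index(["protein", "position"]).index.isin(keep)
    return agg[mask].reset_index(drop=True)


def normality_report(matrix: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk diagnostic per column on observed values.

    Reported, never blocking: downstream steps run regardless.  Columns with
    fewer than three observed values are reported with NaN statistics.
    """
    rows = []
    for column in matrix.columns:
        values = matrix[column].dropna().to_numpy()
        if values.size >= 3:
            stat, p = stats.shapiro(values)
        else:
            stat, p = float("nan"), float("nan")
        rows.append({"column": column, "n_observed": int(values.size),
                     "shapiro_W": float(stat), "p_value": float(p)})
    return pd.DataFrame(rows)


def impute_missing(
    matrix: pd.DataFrame,
    params: QuantParams = QuantParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Downshifted Gaussian imputation of missing log2 intensities.

    Missing entries in each column are drawn from
    ``Normal(col_mean - downshift_sd * col_SD, (impute_width_sd * col_SD)^2)``
    computed on that column's observed values; observed entries are
    untouched.  Deterministic per seed.  A fully missing column is an error
    naming the column.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    for column in out.columns:
        observed = out[column].dropna()
        n_missing = int(out[column].isna().sum())
        if len(observed) == 0:
            raise ValueError(f"column {column!r} is fully missing")
        if n_missing == 0:
            continue
        mean = float(observed.mean())
        sd = float(observed.std(ddof=1)) if len(observed) > 1 else 0.0
        draws = rng.normal(mean - params.downshift_sd * sd,
                           max(params.impute_width_sd * sd, 1e-12),
                           size=n_missing)
        out.loc[out[column].isna(), column] = draws
    return out


def compare_conditions(
    matrix: pd.DataFrame,
    condition_of: dict[str, str],
    params: QuantParams = QuantParams(),
) -> pd.DataFrame:
    """Per-site two-sample t-test between two conditions on a completed
    log2 matrix.

    ``condition_of`` maps column name to condition; exactly two conditions
    with >= 2 replicates each are required.  ``log2fc`` is second condition
    minus first, with conditions ordered by name so the orientation is a
    property of the labels alone: swapping the labels negates fold-changes
    and mirrors the classes.
    Classes: ``<cond2>-enriched`` when log2fc > log2(fc_threshold) and
    p < alpha, ``<cond1>-enriched`` for the mirror case, else ``ns``.
    Sites with zero variance in both groups get ``flagged`` with NaN p.
    """
    conditions = sorted({condition_of[c] for c in matrix.columns})
    if len(conditions) != 2:
        raise ValueError(f"need exactly two conditions, got {conditions}")
    first, second = conditions
    cols1 = [c for c in matrix.columns if condition_of[c] == first]
    cols2 = [c for c in matrix.columns if condition_of[c] == second]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("need >= 2 replicates per condition")

    a = matrix[cols1].to_numpy(float)
    b = matrix[cols2].to_numpy(float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    cutoff = np.log2(params.fc_threshold)

    rows = []
    for i in range(matrix.shape[0]):
        va, vb = a[i], b[i]
        if np.allclose(va.std(), 0) and np.allclose(vb.std(), 0):
            rows.append({"log2fc": float(log2fc[i]), "p_value": float("nan"),
                         "class": "flagged"})
            continue
        _t, p = stats.ttest_ind(vb, va,
                                equal_var=params.equal_variance)
        cls = "ns"
        if p < params.alpha and abs(log2fc[i]) > cutoff:
            cls = (f"{second}-enriched" if log2fc[i] > 0
                   else f"{first}-enriched")
        rows.append({"log2fc": float(log2fc[i]), "p_value": float(p),
                     "class": cls})
    out = pd.DataFrame(rows, index=matrix.index)
    if params.bh_correction:
        p = out["p_value"].to_numpy()
        valid = ~np.isnan(p)
        adj = np.full_like(p, np.nan)
        if valid.sum():
            pv = p[valid]
            order = np.argsort(pv)
            ranked = pv[order] * len(pv) / (np.arange(len(pv)) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            vals = np.empty_like(ranked)
            vals[order] = np.clip(ranked, 0, 1)
            adj[valid] = vals
        out["p_adjusted"] = adj
    return out


def ibaq_prioritize(
    protein_intensity: dict[str, float],
    theoretical_peptides: dict[str, int],
    site_intensity: pd.DataFrame,
) -> pd.DataFrame:
    """Per-site log2(probe-peptide intensity / protein iBAQ).

    iBAQ = protein MS1 intensity / number of theoretical tryptic peptides
    (length-bounded); the ratio flags sites whose probe signal outruns the
    parent protein's abundance — earnest probe targets rather than merely
    abundant proteins.  Proteins with zero theoretical peptides are excluded
    with a warning column; the ranking is invariant to global intensity
    scaling.
    """
    rows = []
    for _idx, row in site_intensity.iterrows():
        protein = row["protein"]
        n_theoretical = theoretical_peptides.get(protein, 0)
        if n_theoretical <= 0:
            continue
        ibaq = protein_intensity[protein] / n_theoretical
        if ibaq <= 0 or row["intensity"] <= 0:
            continue
        rows.append({
            "protein": protein,
            "position": row["position"],
            "ibaq": ibaq,
            "site_intensity": row["intensity"],
            "log2_ratio": float(np.log2(row["intensity"] / ibaq)),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("log2_ratio", ascending=False).reset_index(
            drop=True)
    return out


def volcano_plot(comparison: pd.DataFrame, path=None):
    """Volcano plot of a condition comparison (-log10 p vs log2 fold-change);
    writes a vector figure when a path is given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    x = comparison["log2fc"]
    y = -np.log10(comparison["p_value"])
    classes = comparison["class"]
    for cls, color in zip(sorted(classes.unique()),
                          ("tab:red", "tab:blue", "0.6", "0.3")):
        mask = classes == cls
        ax.scatter(x[mask], y[mask], s=12, label=cls, color=color,
                   alpha=0.8)
    ax.set_xlabel("log2 fold-change")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
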