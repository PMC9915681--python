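"""Group comparison of degeneration metrics across exposure groups.

Every dendrite counts as one observation (N = 1 per dendrite).  For each
metric the module provides:

* a z-score of each treatment against its control,
  ``z = (mean(treatment) - mean(control)) / sd(control)`` -- control-only
  standard deviation, so the score reads as "how many control-sd away the
  treatment mean moved", with the sign encoding direction;
* a one-way ANOVA F-test across groups;
* multiple-comparison adjustment: Bonferroni, or a seeded permutation
  approximation of Dunnett's many-to-one max-|t| null for
  treatment-vs-control designs.

Heatmap export mirrors the usual presentation: a signed z matrix
(metric x group) and a boolean significance matrix at alpha.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import METRIC_NAMES

__all__ = [
    "zscore_vs_control",
    "anova_oneway",
    "adjust_pvalues",
    "dunnett_max_t",
    "compare_groups",
    "export_heatmaps",
]

ALPHA = 0.05


def zscore_vs_control(treatment: Sequence[float], control: Sequence[float]) -> float:
    """z = (mean(treatment) - mean(control)) / sd(control) (control-only sd)."""
    control = np.asarray(control, dtype=float)
    treatment = np.asarray(treatment, dtype=float)
    if control.size < 2:
        raise ValueError("control needs at least 2 values")
    sd = control.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate control (zero standard deviation)")
    return float((treatment.mean() - control.mean()) / sd)


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: between/within mean-square F and its p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def dunnett_max_t(
    treatments: Sequence[Sequence[float]],
    control: Sequence[float],
    n_permutations: int = 999,
    seed: int = 0,
) -> list[float]:
    """Permutation approximation of Dunnett's many-to-one adjusted p-values.

    For each treatment, a two-sample t statistic against the control is
    computed; the family-wise null distribution of ``max |t|`` is estimated
    by permuting group labels ``n_permutations`` times with a fixed seed.
    Each adjusted p-value is the fraction of permutations whose max |t|
    reaches that treatment's observed |t| (add-one estimator).
    """
    rng = np.random.default_rng(seed)
    control = np.asarray(control, dtype=float)
    treatments = [np.asarray(t, dtype=float) for t in treatments]
    sizes = np.array([len(control)] + [len(t) for t in treatments])
    bounds = np.cumsum(sizes)
    pooled = np.concatenate([control] + list(treatments))

    def abs_t(data: np.ndarray) -> np.ndarray:
        """|t| of each treatment vs control; data is (..., N), vectorized."""
        ctrl = data[..., : bounds[0]]
        n0 = sizes[0]
        m0 = ctrl.mean(axis=-1)
        v0 = ctrl.var(axis=-1, ddof=1)
        ts = []
        for i in range(len(treatments)):
            grp = data[..., bounds[i] : bounds[i + 1]]
            ni = sizes[i + 1]
            mi = grp.mean(axis=-1)
            vi = grp.var(axis=-1, ddof=1)
            sp2 = ((n0 - 1) * v0 + (ni - 1) * vi) / (n0 + ni - 2)
            ts.append(np.abs(mi - m0) / np.sqrt(sp2 * (1 / n0 + 1 / ni)))
        return np.stack(ts, axis=-1)

    observed = abs_t(pooled)
    perm_idx = np.argsort(rng.random((n_permutations, len(pooled))), axis=1)
    null_max = abs_t(pooled[perm_idx]).max(axis=-1)
    return [
        float((1 + np.sum(null_max >= t_obs)) / (1 + n_permutations))
        for t_obs in observed
    ]


def adjust_pvalues(
    pvalues: Sequence[float],
    method: str = "bonferroni",
    *,
    treatments: Sequence[Sequence[float]] | None = None,
    control: Sequence[float] | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> list[float]:
    """Multiple-comparison adjustment.

    ``bonferroni``: ``min(1, m * p)``.  ``dunnett_approx``: with raw group
    data (``treatments`` + ``control``) the seeded permutation max-|t|
    approximation of Dunnett's many-to-one test; from p-values alone, the
    Šidák bound ``1 - (1 - p)^m`` (the independent-comparison limit of the
    same family-wise correction).
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if method == "bonferroni":
        return [float(min(1.0, m * x)) for x in p]
    if method == "dunnett_approx":
        if treatments is not None and control is not None:
            return dunnett_max_t(treatments, control, n_permutations, seed)
        return [float(1.0 - (1.0 - x) ** m) for x in p]
    raise ValueError(f"unknown adjustment method: {method!r}")


def compare_groups(
    report: pd.DataFrame,
    groups: pd.DataFrame,
    metrics: Sequence[str] | None = None,
    method: str = "dunnett_approx",
    alpha: float = ALPHA,
    seed: int = 0,
) -> pd.DataFrame:
    """Metric-by-group comparison table from a metric report and a group map.

    ``report`` is the per-dendrite CSV (aggregate ``'all'`` rows are
    ignored); ``groups`` maps ``image_id -> group`` with a boolean
    ``control`` column marking the reference group.  Returns one row per
    (metric, treatment group) with z, raw ANOVA p, adjusted p and a
    significance flag.
    """
    if metrics is None:
        metrics = [m for m in METRIC_NAMES if m != "degeneration_category"]
    df = report[report["dendrite_index"] != "all"].merge(groups, on="image_id")
    ctrl_label = groups.loc[groups["control"].astype(bool), "group"].iloc[0]
    treat_labels = [g for g in groups["group"].unique() if g != ctrl_label]

    rows = []
    for metric in metrics:
        ctrl_vals = df.loc[df["group"] == ctrl_label, metric].dropna().to_numpy()
        treat_vals = [
            df.loc[df["group"] == g, metric].dropna().to_numpy() for g in treat_labels
        ]
        usable = [len(v) >= 2 for v in treat_vals]
        if len(ctrl_vals) < 2 or ctrl_vals.std(ddof=1) == 0 or not any(usable):
            for g in treat_labels:
                rows.append(
                    dict(metric=metric, group=g, z=float("nan"),
                         p_raw=float("nan"), p_adj=float("nan"),
                         significant=False, flag="degenerate control")
                )
            continue
        zs = [
            zscore_vs_control(v, ctrl_vals) if ok else float("nan")
            for v, ok in zip(treat_vals, usable)
        ]
        good = [v for v, ok in zip(treat_vals, usable) if ok]
        _, p_raw = anova_oneway([ctrl_vals] + good)
        if method == "dunnett_approx":
            p_adj_good = dunnett_max_t(good, ctrl_vals, seed=seed)
        else:
            p_adj_good = adjust_pvalues([p_raw] * len(good), method)
        it = iter(p_adj_good)
        for g, z, ok in zip(treat_labels, zs, usable):
            p_adj = next(it) if ok else float("nan")
            rows.append(
                dict(metric=metric, group=g, z=z, p_raw=p_raw, p_adj=p_adj,
                     significant=bool(p_adj < alpha) if math.isfinite(p_adj) else False,
                     flag="")
            )
    return pd.DataFrame(rows)


def export_heatmaps(comparison: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write the signed-z and significance matrices as CSV and a rendered PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    zmat = comparison.pivot(index="metric", columns="group", values="z")
    sig = comparison.pivot(index="metric", columns="group", values="significant")
    z_path = out_dir / "zscores.csv"
    s_path = out_dir / "significant.csv"
    zmat.to_csv(z_path)
    sig.to_csv(s_path)

    fig, axes = plt.subplots(1, 2, figsize=(4 + 2 * zmat.shape[1], 0.4 * len(zmat) + 2))
    vmax = np.nanmax(np.abs(zmat.to_numpy())) or 1.0
    im = axes[0].imshow(zmat.to_numpy(), cmap="coolwarm", vmin=-vmax, vmax=vmax, aspect="auto")
    axes[0].set_title("z score vs control")
    axes[1].imshow(sig.to_numpy().astype(float), cmap="Greys", vmin=0, vmax=1, aspect="auto")
    axes[1].set_title(f"significant (p < {ALPHA})")
    for ax in axes:
        ax.set_xticks(range(zmat.shape[1]), zmat.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(zmat)), zmat.index, fontsize=7)
    fig.colorbar(im, ax=axes[0])
    fig.tight_layout()
    png_path = out_dir / "heatmap.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return {"z": z_path, "significant": s_path, "png": png_path}
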