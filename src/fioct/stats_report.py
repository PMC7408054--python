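"""Statistical comparison layer and cohort report generation.

Tissue classes (TU = tumor core, INF = infiltration zone, BP =
non-neoplastic brain parenchyma) are compared per measurement (attenuation
in mm^-1, normalized fluorescence, cell density in cells/mm^2) with a
classical one-way ANOVA; pairwise contrasts use Welch two-sample t-tests
with Bonferroni correction (p_adj = min(1, m * p) for m comparisons), and
monotone associations are tested with Spearman rank correlation.
Observations are treated as independent; the cohort being emulated pools
several biopsies per patient without a hierarchical model, a documented
limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from fioct.errors import InvalidParameterError

__all__ = [
    "SpearmanResult",
    "oneway_anova",
    "pairwise_bonferroni",
    "spearman",
    "build_report",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class SpearmanResult:
    r_s: float
    p: float
    n: int


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        items = groups.items()
    else:
        items = ((f"group{i}", g) for i, g in enumerate(groups))
    out = {}
    for name, values in items:
        arr = np.asarray(values, dtype=float)
        if arr.size:
            out[str(name)] = arr
    return out


def oneway_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA over >= 2 groups.

    F is the ratio of between- to within-group mean squares with
    (k - 1, N - k) degrees of freedom.  ``groups`` is a mapping
    name -> values or a sequence of value arrays.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise InvalidParameterError("ANOVA needs at least two groups")
    if any(len(v) < 2 for v in gs.values()):
        raise InvalidParameterError("every group needs at least two observations")
    values = list(gs.values())
    pooled = np.concatenate(values)
    ssw = sum(np.sum((v - v.mean()) ** 2) for v in values)
    if ssw == 0 and len({float(v.mean()) for v in values}) == 1:
        raise InvalidParameterError("F undefined: zero within-group variance and equal means")
    f, p = stats.f_oneway(*values)
    return float(f), float(p)


def pairwise_bonferroni(groups, equal_var: bool = False) -> pd.DataFrame:
    """All pairwise two-sample comparisons with Bonferroni adjustment.

    Welch t-tests by default (the variances of tissue classes differ);
    ``p_adj = min(1, m * p)`` over the m = k*(k-1)/2 comparisons.  Returns a
    tidy frame with raw and adjusted p-values and a significance flag at
    the 0.05 level.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise InvalidParameterError("need at least two groups")
    if any(len(v) < 2 for v in gs.values()):
        raise InvalidParameterError("every group needs at least two observations")
    pairs = list(combinations(gs, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        t, praw = stats.ttest_ind(gs[a], gs[b], equal_var=equal_var)
        padj = min(1.0, m * float(praw))
        rows.append({
            "group_a": a, "group_b": b, "t": float(t),
            "p_raw": float(praw), "p_adj": padj,
            "significant": padj < SIGNIFICANCE_LEVEL,
        })
    return pd.DataFrame(rows)


def spearman(x, y, method: str = "asymptotic") -> SpearmanResult:
    """Spearman rank-order correlation.

    Mid-ranks for ties; ``method="asymptotic"`` uses the large-sample
    t-approximation for p, ``method="exact"`` enumerates pairings (only
    sensible for small n).  Constant inputs have no defined correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be equal-length 1D vectors")
    if len(x) < 3:
        raise InvalidParameterError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidParameterError("correlation undefined for constant input")
    if method == "asymptotic":
        res = stats.spearmanr(x, y)
        return SpearmanResult(r_s=float(res.statistic), p=float(res.pvalue), n=len(x))
    if method == "exact":
        def statistic(xp):  # permute pairings of x against fixed y
            return stats.spearmanr(xp, y).statistic

        res = stats.permutation_test(
            (x,), statistic, permutation_type="pairings",
            n_resamples=np.inf if len(x) <= 8 else 20_000,
            alternative="two-sided", random_state=0,
        )
        r = float(stats.spearmanr(x, y).statistic)
        return SpearmanResult(r_s=r, p=float(res.pvalue), n=len(x))
    raise InvalidParameterError(f"unknown method {method!r}")


def build_report(table: pd.DataFrame, out_dir: str | Path | None = None) -> dict:
    """Cohort summary: per-entity/tissue-class statistics, scatter data, tests.

    ``table`` is a tidy per-sample frame with columns ``sample_id``,
    ``entity`` (e.g. LGG/GB/MET), ``tissue`` (TU/INF/BP) and any of
    ``mu_mm1``, ``fl_norm``, ``density_mm2``.  Returns summary tables and,
    when ``out_dir`` is given, writes CSVs and box/scatter figures.
    """
    required = {"sample_id", "entity", "tissue"}
    measures = [c for c in ("mu_mm1", "fl_norm", "density_mm2") if c in table.columns]
    if table.empty:
        return {"summary": pd.DataFrame(), "anova": pd.DataFrame(),
                "pairwise": pd.DataFrame(), "n_samples": 0}
    if missing := required - set(table.columns):
        raise InvalidParameterError(f"report table missing columns {sorted(missing)}")

    summary = (
        table.groupby(["entity", "tissue"])[measures]
        .agg(["median", "mean", "std", "count"])
    )

    anova_rows, pairwise_frames = [], []
    for measure in measures:
        groups = {
            t: sub[measure].dropna().to_numpy()
            for t, sub in table.groupby("tissue")
        }
        groups = {t: v for t, v in groups.items() if len(v) >= 2}
        if len(groups) >= 2:
            f, p = oneway_anova(groups)
            anova_rows.append({"measure": measure, "F": f, "p": p})
            pw = pairwise_bonferroni(groups)
            pw.insert(0, "measure", measure)
            pairwise_frames.append(pw)
    anova = pd.DataFrame(anova_rows)
    pairwise = pd.concat(pairwise_frames, ignore_index=True) if pairwise_frames else pd.DataFrame()

    result = {
        "summary": summary,
        "anova": anova,
        "pairwise": pairwise,
        "n_samples": int(table["sample_id"].nunique()),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "per_sample_values.csv", index=False)
        summary.to_csv(out / "summary_by_entity_tissue.csv")
        anova.to_csv(out / "anova.csv", index=False)
        if not pairwise.empty:
            pairwise.to_csv(out / "pairwise_bonferroni.csv", index=False)
        _write_figures(table, measures, out)
    return result


def _write_figures(table: pd.DataFrame, measures: list[str], out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [t for t in ("BP", "INF", "TU") if t in set(table["tissue"])]
    for measure in measures:
        fig, ax = plt.subplots(figsize=(4, 3))
        data = [table.loc[table["tissue"] == t, measure].dropna() for t in order]
        ax.boxplot(data, tick_labels=order)
        ax.set_ylabel(measure)
        fig.tight_layout()
        fig.savefig(out / f"box_{measure}.png", dpi=120)
        plt.close(fig)

    if "density_mm2" in measures:
        for other, label in (("mu_mm1", "attenuation (mm$^{-1}$)"),
                             ("fl_norm", "normalized fluorescence")):
            if other not in measures:
                continue
            fig, ax = plt.subplots(figsize=(4, 3))
            for tissue, sub in table.groupby("tissue"):
                ax.scatter(sub["density_mm2"], sub[other], label=tissue, s=14)
            ax.set_xlabel("cell density (cells/mm$^2$)")
            ax.set_ylabel(label)
            ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(out / f"scatter_{other}_vs_density.png", dpi=120)
            plt.close(fig)
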