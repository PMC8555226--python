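"""Class-stratified statistical comparison of approved-drug targets vs all targets.

For every centrality metric and every target class (plus the pooled "all"
stratum) the distributions of the "phase4" set (targets of selective
approved drugs) and the "all_target" set are compared with

* a one-tailed two-sample t test, pooled or Welch depending on an F test of
  variance equality (and on gross sample-size imbalance), and
* a Mann-Whitney U test, exact for small samples.

Tests are run one-tailed in the "phase4 more central" direction given by a
fixed orientation map (smaller is more central for average shortest path and
topological coefficient; larger for everything else); the observed direction
of the difference is reported regardless of significance.  Raw p-values are
Benjamini-Hochberg adjusted jointly across metrics, classes and test
families; non-testable cells (fewer than two values in either group after
exclusions) do not count toward the correction factor m.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import LOWER_IS_CENTRAL

ALPHA = 0.05

#: metrics for which zero topological coefficient rows are excluded upstream
T_EXCLUDED_METRICS = ("topological_coefficient", "log_deg_topo")

#: largest min(n) for which the Mann-Whitney test is computed exactly
MW_EXACT_MAX_N = 25


def two_sample_tests(x, y, alternative: str = "greater"):
    """One-tailed t and Mann-Whitney tests of sample ``x`` against ``y``.

    ``alternative`` states the tested direction of x relative to y
    ("greater" or "less").  The t test is pooled-variance unless a two-sided
    F test at alpha=0.05 rejects variance equality or the sample sizes are
    grossly unequal (ratio > 3), in which case Welch's form is used.  The
    Mann-Whitney p is exact when min(n) <= 25 and the data are tie-free,
    otherwise the normal approximation with tie correction is used.

    Returns ``(t_p, mw_p, t_statistic, U)``; the t entries are NaN when both
    samples have zero variance.
    """
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite; exclude undefined values upstream")

    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        t_p, t_stat = np.nan, np.nan
    else:
        if vx > 0 and vy > 0:
            f = vx / vy
            f_p = 2.0 * min(
                stats.f.cdf(f, x.size - 1, y.size - 1),
                stats.f.sf(f, x.size - 1, y.size - 1),
            )
            unequal_var = f_p < ALPHA
        else:
            unequal_var = True
        ratio = max(x.size, y.size) / min(x.size, y.size)
        welch = unequal_var or ratio > 3.0
        t_res = stats.ttest_ind(x, y, equal_var=not welch, alternative=alternative)
        t_p, t_stat = float(t_res.pvalue), float(t_res.statistic)

    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= MW_EXACT_MAX_N and not ties) else "asymptotic"
    mw = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return t_p, float(mw.pvalue), t_stat, float(mw.statistic)


def bh_adjust(raw_ps, m: int | None = None) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    ``m`` is the number of simultaneous tests (defaults to ``len(raw_ps)``);
    it may exceed the number of supplied p-values when some tests are
    reported elsewhere but still count toward the family.
    """
    ps = np.asarray(list(raw_ps), dtype=float)
    if ps.size == 0:
        return []
    if ((ps <= 0) | (ps > 1)).any() or not np.isfinite(ps).all():
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = ps.size
    if m < ps.size:
        raise ValueError("m cannot be smaller than the number of p-values")
    order = np.argsort(ps, kind="mergesort")
    adjusted = np.empty_like(ps)
    running = 1.0
    for rank_from_top in range(ps.size, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, ps[idx] * m / rank_from_top)
        adjusted[idx] = running
    return adjusted.tolist()


def _cell_samples(table, ann, metric, target_class):
    mask = pd.Series(True, index=ann.index)
    if target_class != "all":
        mask = ann["target_class"] == target_class
    values = table[metric].reindex(ann.index)
    if metric in T_EXCLUDED_METRICS:
        t = table["topological_coefficient"].reindex(ann.index)
        mask = mask & (t > 0)
    mask = mask & values.notna()
    x = values[mask & (ann["target_status"] == "phase4")].to_numpy(float)
    y = values[mask & (ann["target_status"] == "all_target")].to_numpy(float)
    return x, y


def stratified_comparison(
    table: pd.DataFrame,
    ann: pd.DataFrame,
    metrics=None,
    classes=None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Compare phase4 vs all-target metric distributions per class.

    Returns one row per (metric, class, test) with raw and BH-adjusted
    p-values, the observed direction, the centrality orientation, group
    sizes and testability.  Rows with fewer than two usable values in either
    group are flagged non-testable and excluded from the BH family.  A
    per-metric average of the raw p-values over all testable pairwise
    comparisons is attached as ``DataFrame.attrs['average_raw_p']``.
    """
    if metrics is None:
        metrics = [c for c in table.columns if c not in ("component", "component_diameter")]
    if classes is None:
        classes = sorted(ann.loc[ann["target_status"] != "other", "target_class"].unique())
    rows = []
    for metric in metrics:
        orientation = (
            "lower_is_central" if metric in LOWER_IS_CENTRAL else "higher_is_central"
        )
        alternative = "less" if orientation == "lower_is_central" else "greater"
        for target_class in list(classes) + ["all"]:
            x, y = _cell_samples(table, ann, metric, target_class)
            testable = x.size >= 2 and y.size >= 2
            if testable:
                t_p, mw_p, t_stat, u_stat = two_sample_tests(x, y, alternative)
                direction = "phase4_higher" if x.mean() > y.mean() else "phase4_lower"
            else:
                t_p = mw_p = t_stat = u_stat = np.nan
                direction = "not_testable"
            for test, raw_p, statistic in (
                ("t_one_tailed", t_p, t_stat),
                ("mann_whitney", mw_p, u_stat),
            ):
                rows.append(
                    {
                        "metric": metric,
                        "target_class": target_class,
                        "test": test,
                        "raw_p": raw_p,
                        "statistic": statistic,
                        "direction": direction,
                        "centrality_orientation": orientation,
                        "n_phase4": x.size,
                        "n_all": y.size,
                        "testable": testable and np.isfinite(raw_p),
                        "alpha": alpha,
                    }
                )
    matrix = pd.DataFrame(rows)
    matrix["adjusted_p"] = np.nan
    mask = matrix["testable"]
    if mask.any():
        matrix.loc[mask, "adjusted_p"] = bh_adjust(matrix.loc[mask, "raw_p"])
    matrix.attrs["average_raw_p"] = (
        matrix[mask].groupby("metric")["raw_p"].mean().to_dict()
    )
    return matrix


def contingency_chi2(table2x2) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) of a 2x2 table."""
    obs = np.asarray(table2x2, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def spearman_r2(x, y) -> float:
    """Squared Spearman rank correlation (mid-ranks for ties); NaN if constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return np.nan
    rho = stats.spearmanr(x, y).statistic
    return float(rho * rho)
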