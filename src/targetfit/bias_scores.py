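"""Knowledge-bias diagnostics, hybrid disease-association scores and GO enrichment.

Annotated protein networks are built from what has been studied, so node
centrality can covary with how extensively a protein appears in the
literature.  This module quantifies that entanglement:

* citation enrichment of approved-drug ("phase4") targets per target class;
* Spearman R^2 between per-node citation counts and each centrality metric;
* OLS regression of per-class centrality significance on per-class citation
  enrichment (a bias signal if significant);
* hybrid target-prioritisation scores mixing a node's disease-association
  percentile with oriented centrality percentiles;
* GO-term frequency enrichment between phase4 and all-target proteins, with
  a two-proportion (Cohen's h, arcsine) power gate at alpha = 0.05.

Percentiles are Hazen mid-rank percentiles, (rank - 0.5) / n with ties
sharing mid-ranks: deterministic, in (0, 1), and invariant under strictly
monotone transforms of the underlying counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .centrality import LOWER_IS_CENTRAL
from .compare_stats import T_EXCLUDED_METRICS

ALPHA = 0.05


def percentile_ranks(values) -> pd.Series:
    """Hazen percentiles (rank - 0.5)/n with mid-ranks for ties, in (0, 1)."""
    s = pd.Series(values, dtype=float)
    return (s.rank(method="average") - 0.5) / s.notna().sum()


def citation_enrichment(ann: pd.DataFrame) -> pd.DataFrame:
    """Per-class and overall citation totals of phase4 vs all targets.

    ``citations_all`` sums over both target sets (phase4 plus all_target);
    ``fraction_phase4`` is the phase4 share of those citations;
    ``relative_abundance`` divides the phase4 citation fraction by the
    phase4 protein-count fraction within the class.
    """
    targets = ann[ann["target_status"].isin(["phase4", "all_target"])]
    rows = []
    class_values = ["all"] + sorted(targets["target_class"].unique())
    for cls in class_values:
        sub = targets if cls == "all" else targets[targets["target_class"] == cls]
        is_p4 = sub["target_status"] == "phase4"
        cit_all = int(sub["citations"].sum())
        cit_p4 = int(sub.loc[is_p4, "citations"].sum())
        n_all, n_p4 = len(sub), int(is_p4.sum())
        if n_p4 == 0:
            frac, rel = 0.0, 0.0
        elif cit_all == 0:
            frac, rel = np.nan, np.nan  # flagged: class without citations
        else:
            frac = cit_p4 / cit_all
            protein_frac = n_p4 / n_all
            rel = frac / protein_frac if protein_frac > 0 else np.nan
        rows.append(
            {
                "target_class": cls,
                "citations_all": cit_all,
                "citations_phase4": cit_p4,
                "n_all": n_all,
                "n_phase4": n_p4,
                "fraction_phase4": frac,
                "relative_abundance": rel,
            }
        )
    return pd.DataFrame(rows).set_index("target_class")


def centrality_citation_correlation(
    table: pd.DataFrame, ann: pd.DataFrame, metrics=None
) -> pd.Series:
    """Spearman R^2 between citation counts and each centrality metric."""
    if metrics is None:
        metrics = [c for c in table.columns if c not in ("component", "component_diameter")]
    citations = ann["citations"].reindex(table.index).astype(float)
    if (citations.notna().sum()) < 10:
        raise ValueError("need >= 10 nodes with citation counts")
    out = {}
    for metric in metrics:
        values = table[metric]
        mask = values.notna() & citations.notna()
        if metric in T_EXCLUDED_METRICS:
            mask &= table["topological_coefficient"] > 0
        x = citations[mask].to_numpy()
        y = values[mask].to_numpy(float)
        if np.unique(x).size < 2 or np.unique(y).size < 2 or x.size < 3:
            out[metric] = np.nan
            continue
        rho = stats.spearmanr(x, y).statistic
        out[metric] = float(rho * rho)
    return pd.Series(out, name="spearman_r2")


def enrichment_vs_significance_regression(enrichment, neglog_adj_p) -> tuple[float, float]:
    """OLS of -log10 adjusted p on citation enrichment across target classes.

    Returns (signed adjusted R, regression p): the sign of the slope times
    the square root of the adjusted R^2 (floored at 0), as in spreadsheet
    regression summaries.
    """
    x = np.asarray(list(enrichment), dtype=float)
    y = np.asarray(list(neglog_adj_p), dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired class values")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = model.params[1]
    adj_r = np.sign(slope) * np.sqrt(max(model.rsquared_adj, 0.0))
    return float(adj_r), float(model.f_pvalue)


def hybrid_scores(
    table: pd.DataFrame,
    ann: pd.DataFrame,
    log_deg_topo_orientation: str = "higher_is_central",
) -> pd.DataFrame:
    """Hybrid disease-association / centrality prioritisation scores.

    R is the percentile of the disease-association count.  Components are
    oriented so that "more central" maps to higher percentile:

    * ``rns_like``  = mean(R, degree percentile, 1 - asp percentile)
    * ``r_top``     = mean(R, 1 - topological-coefficient percentile)
    * ``r_top_degree`` = mean(R, oriented percentile of log10(k*T)); the
      orientation defaults to higher-is-central and should follow the
      network-wide phase4 direction from the stratified comparison.

    All scores lie in [0, 1]; rows missing a centrality component are NaN
    for the affected score.
    """
    r = percentile_ranks(ann["disease_associations"].reindex(table.index))
    deg_p = percentile_ranks(table["degree"])
    scores = pd.DataFrame(index=table.index)
    scores["R"] = r
    if "average_shortest_path" in table:
        asp_p = percentile_ranks(table["average_shortest_path"])
        scores["rns_like"] = (r + deg_p + (1.0 - asp_p)) / 3.0
    topo = table["topological_coefficient"].where(table["topological_coefficient"] > 0)
    topo_p = percentile_ranks(topo)
    scores["r_top"] = (r + (1.0 - topo_p)) / 2.0
    ldt_p = percentile_ranks(table["log_deg_topo"])
    if log_deg_topo_orientation == "lower_is_central":
        ldt_p = 1.0 - ldt_p
    scores["r_top_degree"] = (r + ldt_p) / 2.0
    return scores


def two_proportion_power(h: float, n1: int, n2: int, alpha: float = ALPHA) -> float:
    """Power of a two-sided two-proportion z test at effect size Cohen's h."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    z_eff = abs(h) * np.sqrt(n1 * n2 / (n1 + n2))
    return float(stats.norm.cdf(z_eff - z_alpha) + stats.norm.cdf(-z_eff - z_alpha))


def go_enrichment(
    ann: pd.DataFrame,
    coverage: float = 0.95,
    power_threshold: float = 0.8,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """GO-term frequency enrichment of phase4 vs all-target proteins.

    Terms are ranked by total association count over all annotated nodes and
    truncated at the minimal prefix reaching ``coverage`` of associations.
    Per term: the fraction of proteins carrying it in each group, the
    enrichment ratio and normalised difference, Cohen's h, and the power of
    a two-proportion test at the groups' protein counts.  ``flagged`` marks
    twofold enrichment or depletion; ``powered`` marks power > 0.8.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    counts: dict[str, int] = {}
    for terms in ann["go_terms"]:
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    if not counts:
        raise ValueError("no GO terms present")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(counts.values())
    kept, acc = [], 0
    for term, c in ranked:
        kept.append(term)
        acc += c
        if acc / total >= coverage:
            break

    p4 = ann[ann["target_status"] == "phase4"]
    allt = ann[ann["target_status"] == "all_target"]
    n1, n2 = len(p4), len(allt)
    rows = []
    for term in kept:
        if n1 == 0 or n2 == 0:
            rows.append({"term": term, "evaluable": False})
            continue
        f1 = sum(term in t for t in p4["go_terms"]) / n1
        f2 = sum(term in t for t in allt["go_terms"]) / n2
        ratio = f1 / f2 if f2 > 0 else np.inf if f1 > 0 else np.nan
        norm_diff = (f1 - f2) / f2 if f2 > 0 else np.nan
        h = abs(2.0 * np.arcsin(np.sqrt(f1)) - 2.0 * np.arcsin(np.sqrt(f2)))
        power = two_proportion_power(h, n1, n2, alpha)
        flagged = bool(ratio >= 2.0 or ratio <= 0.5) if np.isfinite(ratio) else bool(f1 > 0 or f2 > 0)
        rows.append(
            {
                "term": term,
                "freq_phase4": f1,
                "freq_all": f2,
                "enrichment_ratio": ratio,
                "normalized_difference": norm_diff,
                "effect_size_h": h,
                "power": power,
                "flagged": flagged,
                "powered": bool(power > power_threshold),
                "evaluable": True,
            }
        )
    return pd.DataFrame(rows).set_index("term")
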