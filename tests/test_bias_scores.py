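"""Knowledge-bias diagnostics, hybrid scores and GO enrichment."""

import numpy as np
import pandas as pd
import pytest

from targetfit import bias_scores
from targetfit.bias_scores import (
    centrality_citation_correlation,
    citation_enrichment,
    enrichment_vs_significance_regression,
    go_enrichment,
    hybrid_scores,
    percentile_ranks,
    two_proportion_power,
)
from targetfit.centrality import compute_centrality_table
from targetfit.synthetic_data import SynthConfig, synth_study


def make_ann(rows):
    ann = pd.DataFrame(rows).set_index("node")
    ann["go_terms"] = ann.get("go_terms", pd.Series([frozenset()] * len(ann), index=ann.index))
    for col in ("citations", "disease_associations"):
        if col not in ann:
            ann[col] = 0
    return ann


class TestCitationEnrichment:
    def test_printed_class_totals_reproduce_fractions(self):
        """Aggregate citation totals per class reproduce the published
        phase4 citation fractions (0.12 overall, 0.23 kinases, 0.56 NRs)."""
        rows = []
        totals = {  # (all citations, phase4 citations) per class
            "channel_transporter": (65138, 2708),
            "enzyme": (601619, 54934),
            "gpcr": (59071, 6294),
            "kinase": (471280, 107867),
            "nuclear_receptor": (62657, 35015),
            "other": (522043, 1967),
        }
        for cls, (cit_all, cit_p4) in totals.items():
            rows.append({"node": f"{cls}_p4", "target_status": "phase4",
                         "target_class": cls, "citations": cit_p4})
            rows.append({"node": f"{cls}_bg", "target_status": "all_target",
                         "target_class": cls, "citations": cit_all - cit_p4})
        table = citation_enrichment(make_ann(rows))
        assert table.loc["all", "fraction_phase4"] == pytest.approx(0.12, abs=0.005)
        assert table.loc["kinase", "fraction_phase4"] == pytest.approx(0.23, abs=0.005)
        assert table.loc["nuclear_receptor", "fraction_phase4"] == pytest.approx(0.56, abs=0.005)

    def test_class_without_phase4(self):
        rows = [
            {"node": "a", "target_status": "all_target", "target_class": "gpcr",
             "citations": 10},
            {"node": "b", "target_status": "all_target", "target_class": "gpcr",
             "citations": 5},
        ]
        table = citation_enrichment(make_ann(rows))
        assert table.loc["gpcr", "fraction_phase4"] == 0.0
        assert table.loc["gpcr", "relative_abundance"] == 0.0

    def test_class_sums_add_to_overall(self):
        _, ann = synth_study(SynthConfig(n_nodes=400, seed=4))
        table = citation_enrichment(ann)
        per_class = table.drop(index="all")
        assert per_class["citations_all"].sum() == table.loc["all", "citations_all"]
        assert per_class["citations_phase4"].sum() == table.loc["all", "citations_phase4"]
        ok = table["fraction_phase4"].dropna()
        assert ((ok >= 0) & (ok <= 1)).all()


class TestCitationCorrelation:
    def test_copula_rho_recovered_as_r2(self):
        r2s = []
        for seed in range(5):
            g, ann = synth_study(SynthConfig(n_nodes=3000, seed=seed, citation_rank_rho=0.4))
            table = compute_centrality_table(g, include_path_metrics=False)
            r2s.append(centrality_citation_correlation(table, ann, ["degree"])["degree"])
        assert np.mean(r2s) == pytest.approx(0.16, abs=0.05)

    def test_null_rho_gives_near_zero(self):
        g, ann = synth_study(SynthConfig(n_nodes=3000, seed=1, citation_rank_rho=0.0))
        table = compute_centrality_table(g, include_path_metrics=False)
        assert centrality_citation_correlation(table, ann, ["degree"])["degree"] < 0.01

    def test_constant_citations_flagged(self):
        g, ann = synth_study(SynthConfig(n_nodes=300, seed=2))
        ann["citations"] = 5
        table = compute_centrality_table(g, include_path_metrics=False)
        assert np.isnan(centrality_citation_correlation(table, ann, ["degree"])["degree"])


class TestEnrichmentRegression:
    def test_exact_linear_extremes(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        up = [2.0, 4.0, 6.0, 8.0, 10.0]
        r, _ = enrichment_vs_significance_regression(x, up)
        assert r == pytest.approx(1.0)
        r, _ = enrichment_vs_significance_regression(x, up[::-1])
        assert r == pytest.approx(-1.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            enrichment_vs_significance_regression([1, 2, 3], [1, 2, 3])

    def test_null_calibration(self, rng):
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            _, p = enrichment_vs_significance_regression(
                rng.normal(size=5), rng.normal(size=5)
            )
            hits += p < 0.05
        assert 0.02 <= hits / n_rep <= 0.08


class TestHybridScores:
    def test_all_tied_scores_half(self):
        table = pd.DataFrame(
            {
                "degree": 5.0,
                "average_shortest_path": 2.0,
                "topological_coefficient": 0.5,
                "log_deg_topo": 0.4,
            },
            index=[f"n{i}" for i in range(8)],
        )
        ann = make_ann(
            [{"node": f"n{i}", "target_status": "other", "target_class": "other",
              "disease_associations": 3} for i in range(8)]
        )
        scores = hybrid_scores(table, ann)
        assert np.allclose(scores["rns_like"], 0.5)
        assert np.allclose(scores["r_top"], 0.5)
        assert np.allclose(scores["r_top_degree"], 0.5)

    def test_mean_arithmetic_and_bounds(self):
        _, ann = synth_study(SynthConfig(n_nodes=500, seed=6))
        g, _ = synth_study(SynthConfig(n_nodes=500, seed=6))
        table = compute_centrality_table(g)
        scores = hybrid_scores(table, ann)
        for col in ("rns_like", "r_top", "r_top_degree"):
            vals = scores[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()

    def test_percentiles_invariant_to_monotone_transform(self, rng):
        x = rng.lognormal(size=50)
        assert np.allclose(percentile_ranks(x), percentile_ranks(np.log(x)))
        assert np.allclose(percentile_ranks(x), percentile_ranks(x**3))


class TestGOEnrichment:
    def test_power_formula_h_half_n64(self):
        assert two_proportion_power(0.5, 64, 64) == pytest.approx(0.80, abs=0.01)

    def test_null_term_power_at_alpha(self):
        rows = []
        for i in range(40):
            rows.append({"node": f"p{i}", "target_status": "phase4",
                         "target_class": "kinase", "go_terms": frozenset({"GO:1"})})
            rows.append({"node": f"a{i}", "target_status": "all_target",
                         "target_class": "kinase", "go_terms": frozenset({"GO:1"})})
        table = go_enrichment(make_ann(rows))
        row = table.loc["GO:1"]
        assert row["enrichment_ratio"] == pytest.approx(1.0)
        assert row["effect_size_h"] == 0.0
        assert row["power"] == pytest.approx(0.05, abs=1e-6)
        assert not row["flagged"]

    def test_fourfold_enrichment_flagged(self):
        rows = []
        for i in range(10):
            rows.append({"node": f"p{i}", "target_status": "phase4", "target_class": "gpcr",
                         "go_terms": frozenset({"GO:hi"} if i < 4 else ())})
        for i in range(100):
            rows.append({"node": f"a{i}", "target_status": "all_target", "target_class": "gpcr",
                         "go_terms": frozenset({"GO:hi"} if i < 10 else {"GO:bg"})})
        table = go_enrichment(make_ann(rows), coverage=1.0)
        row = table.loc["GO:hi"]
        assert row["enrichment_ratio"] == pytest.approx(4.0)
        assert row["flagged"]

    def test_coverage_keeps_minimal_prefix(self):
        rows = []
        # GO:a on 90 nodes, GO:b on 9, GO:c on 1 -> 95% coverage needs a+b
        for i in range(90):
            rows.append({"node": f"x{i}", "target_status": "all_target",
                         "target_class": "other", "go_terms": frozenset({"GO:a"})})
        for i in range(9):
            rows.append({"node": f"y{i}", "target_status": "phase4",
                         "target_class": "other", "go_terms": frozenset({"GO:b"})})
        rows.append({"node": "z", "target_status": "phase4", "target_class": "other",
                     "go_terms": frozenset({"GO:c"})})
        table = go_enrichment(make_ann(rows), coverage=0.95)
        assert set(table.index) == {"GO:a", "GO:b"}

    def test_power_monotone_in_h_and_n(self):
        assert two_proportion_power(0.6, 64, 64) > two_proportion_power(0.4, 64, 64)
        assert two_proportion_power(0.5, 128, 128) > two_proportion_power(0.5, 32, 32)
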