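"""RPM normalization, fold-change enrichment, gene hit calls, concordance."""

import math

import numpy as np
import pandas as pd
import pytest

from senescreen import (
    AnalysisError,
    AnalysisParams,
    CountingError,
    analyze_screen,
    call_gene_hits,
    compute_enrichment,
    evaluate_hits,
    make_random_library,
    normalize_rpm,
    replicate_concordance,
    run_screen_analysis,
    simulate_screen,
    SimConfig,
)
from conftest import make_count_matrix

ROLES4 = {"baseline": "baseline", "ctrl": "no_dox", "dox1": "dox", "dox2": "dox"}


class TestNormalize:
    def test_equal_counts_split_the_million(self):
        cm = make_count_matrix({"s": [2, 2]}, {"s": "baseline"}, ["a", "b"])
        rpm = normalize_rpm(cm)
        assert list(rpm["s"]) == [5e5, 5e5]

    def test_columns_sum_to_one_million(self, small_lib):
        cm, _ = simulate_screen(SimConfig(library=small_lib, seq_depth=33333, seed=2))
        rpm = normalize_rpm(cm)
        np.testing.assert_allclose(rpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_count_gives_zero_rpm(self):
        cm = make_count_matrix({"s": [0, 4]}, {"s": "baseline"}, ["a", "b"])
        assert normalize_rpm(cm)["s"]["a"] == 0.0

    def test_zero_total_sample_named_in_error(self):
        cm = make_count_matrix({"s": [0, 0], "t": [1, 1]},
                               {"s": "baseline", "t": "dox"}, ["a", "b"])
        with pytest.raises(AnalysisError, match="'s'"):
            normalize_rpm(cm)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 1000, 30)
        cm = make_count_matrix({"s": list(vals)}, {"s": "baseline"},
                               [f"h{i}" for i in range(30)])
        rpm = normalize_rpm(cm)["s"]
        assert (rpm.rank() == pd.Series(vals, index=rpm.index).rank()).all()


def four_sample_cm(base, ctrl, dox1, dox2, ids):
    return make_count_matrix(
        {"baseline": base, "ctrl": ctrl, "dox1": dox1, "dox2": dox2},
        ROLES4, ids)


class TestEnrichment:
    def test_hand_computed_fold_change(self):
        # target hairpin: baseline/ctrl RPM 10, dox RPM 80 each, 500 raw reads
        cm = four_sample_cm(
            base=[10, 999990], ctrl=[10, 999990],
            dox1=[500, 6249500], dox2=[500, 6249500],
            ids=["hit", "filler"])
        et = compute_enrichment(cm, AnalysisParams())
        row = et.loc["hit"]
        assert row["fc_vs_baseline"] == pytest.approx(80.5 / 10.5)
        assert row["fc_vs_control"] == pytest.approx(80.5 / 10.5)
        assert row["passes_read_filter"] and row["enriched"]

    def test_read_filter_blocks_low_coverage(self):
        # huge fold change but 60/90 raw dox reads: fails the >100 filter
        cm = four_sample_cm(
            base=[1, 999999], ctrl=[1, 999999],
            dox1=[60, 999940], dox2=[90, 999910],
            ids=["low", "filler"])
        et = compute_enrichment(cm, AnalysisParams(read_filter_mode="any_dox"))
        assert et.loc["low", "fc_vs_baseline"] > 5
        assert not et.loc["low", "passes_read_filter"]
        assert not et.loc["low", "enriched"]

    def test_any_vs_all_dox_filter_modes(self):
        cm = four_sample_cm(
            base=[1, 999999], ctrl=[1, 999999],
            dox1=[150, 999850], dox2=[90, 999910],
            ids=["h", "filler"])
        any_mode = compute_enrichment(cm, AnalysisParams(read_filter_mode="any_dox"))
        all_mode = compute_enrichment(cm, AnalysisParams(read_filter_mode="all_dox"))
        assert any_mode.loc["h", "passes_read_filter"]
        assert not all_mode.loc["h", "passes_read_filter"]

    def test_all_equal_rpm_gives_unit_fold_change(self):
        cm = four_sample_cm([5, 5], [5, 5], [5, 5], [5, 5], ["a", "b"])
        et = compute_enrichment(cm)
        assert (et["fc_vs_baseline"] == 1.0).all()
        assert (et["fc_vs_control"] == 1.0).all()
        assert not et["enriched"].any()

    def test_replicate_mode_both_needs_every_replicate(self):
        # rep1 far above 5x, rep2 below: mean passes, 'both' does not
        cm = four_sample_cm(
            base=[10, 999990], ctrl=[10, 999990],
            dox1=[900, 5624100], dox2=[200, 5624800],
            ids=["h", "filler"])
        # RPM: dox1 160, dox2 ~35.6 -> mean ~97.8 (fc ~9.3); rep2 fc ~3.4
        mean_mode = compute_enrichment(cm, AnalysisParams(replicate_mode="mean"))
        both_mode = compute_enrichment(cm, AnalysisParams(replicate_mode="both"))
        assert mean_mode.loc["h", "enriched"]
        assert not both_mode.loc["h", "enriched"]

    def test_missing_role_rejected(self):
        cm = make_count_matrix({"baseline": [1, 2], "dox1": [1, 2]},
                               {"baseline": "baseline", "dox1": "dox"},
                               ["a", "b"])
        with pytest.raises(AnalysisError, match="no_dox"):
            compute_enrichment(cm)

    def test_two_baselines_rejected(self):
        cm = make_count_matrix(
            {"b1": [1], "b2": [1], "c": [1], "d": [1]},
            {"b1": "baseline", "b2": "baseline", "c": "no_dox", "d": "dox"},
            ["a"])
        with pytest.raises(CountingError, match="exactly one baseline"):
            compute_enrichment(cm)


class TestGeneHits:
    def _et(self, flags):
        return pd.DataFrame({"enriched": flags},
                            index=pd.Index([f"s{i}" for i in range(len(flags))],
                                           name="shrna_id"))

    def test_two_enriched_hairpins_make_a_hit(self, small_lib):
        ids = small_lib.shrna_ids
        flags = pd.Series(False, index=pd.Index(ids, name="shrna_id"))
        g0 = small_lib.genes[0]
        g0_shrnas = [s for s in ids if small_lib.gene_of[s] == g0]
        flags[g0_shrnas[:2]] = True  # (T,T,F,F,F)
        hits = call_gene_hits(pd.DataFrame({"enriched": flags}), small_lib)
        row = hits.set_index("gene").loc[g0]
        assert row["hit"] and row["n_enriched"] == 2
        assert set(row["supporting_shrnas"].split(",")) == set(g0_shrnas[:2])
        # a single enriched hairpin is not enough
        flags[:] = False
        flags[g0_shrnas[0]] = True
        hits = call_gene_hits(pd.DataFrame({"enriched": flags}), small_lib)
        assert not hits.set_index("gene").loc[g0, "hit"]

    def test_matches_brute_force_oracle_on_random_flags(self):
        lib = make_random_library(200, (5, 6), 14, 0, seed=12)
        rng = np.random.default_rng(1)
        flags = pd.Series(rng.random(len(lib)) < 0.1,
                          index=pd.Index(lib.shrna_ids, name="shrna_id"))
        hits = call_gene_hits(pd.DataFrame({"enriched": flags}), lib,
                              AnalysisParams(min_shrnas=2))
        # independent two-line rule: count enriched per gene, hit iff >= 2
        per_gene = {}
        for sid, f in flags.items():
            per_gene[lib.gene_of[sid]] = per_gene.get(lib.gene_of[sid], 0) + int(f)
        expected = {g for g, n in per_gene.items() if n >= 2}
        assert set(hits.loc[hits["hit"], "gene"]) == expected

    def test_unknown_shrna_rejected(self, small_lib):
        et = pd.DataFrame({"enriched": [True]},
                          index=pd.Index(["ghost"], name="shrna_id"))
        with pytest.raises(AnalysisError, match="absent from library"):
            call_gene_hits(et, small_lib)

    def test_sorted_by_support_then_gene(self, small_lib):
        ids = small_lib.shrna_ids
        flags = pd.Series(False, index=pd.Index(ids, name="shrna_id"))
        flags[[s for s in ids if small_lib.gene_of[s] == small_lib.genes[3]][:3]] = True
        flags[[s for s in ids if small_lib.gene_of[s] == small_lib.genes[1]][:2]] = True
        hits = call_gene_hits(pd.DataFrame({"enriched": flags}), small_lib)
        assert list(hits["n_enriched"])[:2] == [3, 2]
        tail = hits.iloc[2:]
        assert list(tail["gene"]) == sorted(tail["gene"])


class TestConcordance:
    def test_duplicate_columns_correlate_perfectly(self):
        vals = [10, 200, 3000, 40]
        cm = make_count_matrix(
            {"baseline": vals, "d1": vals, "d2": vals},
            {"baseline": "baseline", "d1": "dox", "d2": "dox"},
            ["a", "b", "c", "d"])
        r, paired = replicate_concordance(cm)
        assert r == pytest.approx(1.0)
        assert paired.shape == (4, 2)

    def test_geometric_anti_ordered_vectors(self):
        # log2 RPM of (1,2,4) vs (4,2,1) is anti-collinear
        cm = make_count_matrix(
            {"baseline": [1, 1, 1], "d1": [1, 2, 4], "d2": [4, 2, 1]},
            {"baseline": "baseline", "d1": "dox", "d2": "dox"},
            ["a", "b", "c"])
        r, _ = replicate_concordance(cm, pseudocount_rpm=1e-9)
        assert r == pytest.approx(-1.0, abs=1e-6)

    def test_single_replicate_rejected(self):
        cm = make_count_matrix({"baseline": [1], "d1": [1]},
                               {"baseline": "baseline", "d1": "dox"}, ["a"])
        with pytest.raises(AnalysisError, match="need >= 2"):
            replicate_concordance(cm)

    def test_multinomial_replicates_highly_concordant(self):
        rng = np.random.default_rng(5)
        abund = rng.lognormal(mean=0, sigma=1.0, size=2000)
        p = abund / abund.sum()
        d1 = rng.multinomial(10**6, p)
        d2 = rng.multinomial(10**6, p)
        cm = make_count_matrix(
            {"baseline": list(d1), "d1": list(d1), "d2": list(d2)},
            {"baseline": "baseline", "d1": "dox", "d2": "dox"},
            [f"h{i}" for i in range(2000)])
        r, _ = replicate_concordance(cm)
        assert r >= 0.95


class TestPipeline:
    def _simulate_to_disk(self, tmp_path, seed=1, **overrides):
        from senescreen import write_library, write_truth

        lib = make_random_library(100, (5, 5), 14, 3, seed=seed)
        cfg = SimConfig(library=lib, frac_escape_genes=0.05,
                        seq_depth=10**6, seed=seed, **overrides)
        cm, truth = simulate_screen(cfg)
        write_library(lib, tmp_path / "library.tsv")
        cm.write(tmp_path / "counts.tsv", tmp_path / "samples.tsv")
        write_truth(truth, lib, tmp_path / "truth.tsv")
        return lib, truth

    def test_recovers_planted_genes_and_consistent_attrition(self, tmp_path):
        lib, truth = self._simulate_to_disk(tmp_path)
        et, hits, report = run_screen_analysis(
            tmp_path / "counts.tsv", tmp_path / "samples.tsv",
            tmp_path / "library.tsv", tmp_path / "out")
        hit_genes = set(report["hit_genes"])
        assert len(hit_genes & truth.escape_genes) >= 0.5 * len(truth.escape_genes)
        att = report["attrition"]
        assert att["enriched"] <= att["passing_read_filter"] <= att["shrnas_in"]
        assert att["genes_hit"] == len(hit_genes)
        assert (tmp_path / "out" / "enrichment.tsv").exists()
        assert (tmp_path / "out" / "report.json").exists()

    def test_infinite_threshold_yields_nothing(self, tmp_path):
        self._simulate_to_disk(tmp_path)
        _, _, report = run_screen_analysis(
            tmp_path / "counts.tsv", tmp_path / "samples.tsv",
            tmp_path / "library.tsv", tmp_path / "out",
            AnalysisParams(fc_threshold=float("inf")))
        assert report["attrition"]["enriched"] == 0
        assert report["attrition"]["genes_hit"] == 0

    def test_outputs_byte_identical_across_runs(self, tmp_path):
        self._simulate_to_disk(tmp_path)
        args = (tmp_path / "counts.tsv", tmp_path / "samples.tsv",
                tmp_path / "library.tsv")
        run_screen_analysis(*args, tmp_path / "o1")
        run_screen_analysis(*args, tmp_path / "o2")
        for name in ("enrichment.tsv", "gene_hits.tsv", "report.json"):
            assert (tmp_path / "o1" / name).read_bytes() == \
                   (tmp_path / "o2" / name).read_bytes()


class TestEvaluate:
    def test_perfect_recovery(self):
        hits = pd.DataFrame({"gene": ["A", "B"], "hit": [True, True]})
        truth = pd.DataFrame({"gene": ["A", "B", "C"],
                              "escape_gene": [1, 1, 0]})
        out = evaluate_hits(hits, truth)
        assert out["sensitivity"] == 1.0 and out["precision"] == 1.0

    def test_empty_hit_list(self):
        hits = pd.DataFrame({"gene": ["A"], "hit": [False]})
        truth = pd.DataFrame({"gene": ["A"], "escape_gene": [1]})
        out = evaluate_hits(hits, truth)
        assert out["sensitivity"] == 0.0 and out["precision"] is None

    def test_matches_hand_confusion_counts(self):
        hits = pd.DataFrame({"gene": list("ABCDE"),
                             "hit": [True, True, True, False, False]})
        truth = pd.DataFrame({"gene": list("ABCDEF"),
                              "escape_gene": [1, 0, 0, 1, 0, 1]})
        out = evaluate_hits(hits, truth)
        assert (out["true_positives"], out["false_positives"],
                out["false_negatives"]) == (1, 2, 2)
        assert out["sensitivity"] == pytest.approx(1 / 3)
        assert out["precision"] == pytest.approx(1 / 3)

    def test_disjoint_namespaces_rejected(self):
        hits = pd.DataFrame({"gene": ["X", "Y"], "hit": [True, False]})
        truth = pd.DataFrame({"gene": ["A", "B"], "escape_gene": [1, 0]})
        with pytest.raises(AnalysisError, match="disjoint"):
            evaluate_hits(hits, truth)


def test_params_validation():
    with pytest.raises(AnalysisError):
        AnalysisParams(fc_threshold=0)
    with pytest.raises(AnalysisError):
        AnalysisParams(pseudocount_rpm=0)
    with pytest.raises(AnalysisError):
        AnalysisParams(read_filter_mode="pooled")
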