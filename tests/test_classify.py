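"""Cohort calling, overlap statistics, operon/TF/promoter/fitness analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coldshock.annotation import GenomeAnnotation
from coldshock.classify import (at_lfc_correlation, at_richness, call_csr,
                                find_paired_promoters, fitness_variability,
                                fold_enrichment, lfc_slice,
                                operon_pair_analysis, overlap_stats,
                                select_reporters, strong_response,
                                tf_propagation)
from coldshock.synth import SynthSpec, generate_annotation, generate_lfc_tables


def _table(records):
    return pd.DataFrame(records, columns=["gene_id", "lfc", "pvalue"])


class TestCallCsr:
    def test_rule(self):
        cs = _table([("a", -0.5, 0.01), ("b", -0.5, 0.2), ("c", -0.5, 0.01),
                     ("d", 0.5, 0.01)])
        ctrl = _table([("a", 0.1, 0.01), ("b", 0.1, 0.01), ("c", -0.1, 0.01),
                       ("d", 0.1, 0.01)])
        result = call_csr(cs, ctrl)
        # a: repressed + significant control drift -> CSR
        # b: CS not significant; c: control decreasing; d: not repressed
        assert result.genes == {"a"}

    def test_missing_records_logged(self):
        cs = _table([("a", -0.5, 0.01)])
        ctrl = _table([("a", 0.1, 0.01), ("b", 0.1, 0.01)])
        result = call_csr(cs, ctrl)
        assert result.excluded == {"b": "missing CS record"}

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            call_csr(_table([]), _table([]))


class TestStrongResponse:
    @pytest.mark.parametrize("lfc, p, expected", [
        (0.9, 0.01, True),
        (-0.9, 0.01, True),
        (0.8, 0.01, False),   # strict threshold
        (0.9, 0.06, False),
        (0.9, 0.05, False),   # strict alpha
    ])
    def test_boundaries(self, lfc, p, expected):
        result = strong_response(_table([("a", lfc, p)]), threshold=0.8)
        assert ("a" in result.genes) is expected

    def test_novobiocin_threshold_is_half_the_cs_threshold(self):
        from coldshock.classify import (STRONG_CS_THRESHOLD,
                                        STRONG_NOVO_THRESHOLD)
        assert STRONG_NOVO_THRESHOLD == STRONG_CS_THRESHOLD / 2
        assert STRONG_NOVO_THRESHOLD == 0.4


class TestOverlap:
    def test_printed_counts_give_the_published_odds_ratio(self):
        """a=147, |A|=381, |B|=1161, N=4328 -> OR = 1.82 to two decimals."""
        A = {f"csr{i}" for i in range(381)}
        B = {f"csr{i}" for i in range(147)} | {f"sc{i}" for i in range(1161 - 147)}
        st_ = overlap_stats(A, B, 4328)
        assert (st_.a, st_.b, st_.c, st_.d) == (147, 234, 1014, 2933)
        assert round(st_.odds_ratio, 2) == 1.82
        assert st_.fisher_p < 0.05
        assert st_.expected_overlap == pytest.approx(381 * 1161 / 4328)

    def test_independent_sets_have_unit_median_odds_ratio(self):
        rng = np.random.default_rng(20)
        universe = np.arange(2000)
        ors = []
        for _ in range(300):
            A = set(rng.choice(universe, 300, replace=False))
            B = set(rng.choice(universe, 500, replace=False))
            ors.append(overlap_stats(A, B, 2000).odds_ratio)
        assert np.median(ors) == pytest.approx(1.0, abs=0.1)

    def test_subset_flags_undefined_odds_ratio(self):
        A = {"a", "b"}
        B = {"a", "b", "c"}
        st_ = overlap_stats(A, B, 10)
        assert st_.flag_or_undefined
        assert np.isnan(st_.odds_ratio)


def test_fold_enrichment_limits_and_brute_force():
    universe = [f"g{i}" for i in range(20)]
    cohort = universe[:5]
    tags = {"all": set(universe), "tag": set(universe[:8])}
    df = fold_enrichment(cohort, tags, 20).set_index("tag")
    assert df.loc["all", "fold_enrichment"] == pytest.approx(1.0)
    # brute force: enumerate all C(20,5) cohorts, count overlap >= observed
    obs = int(df.loc["tag", "observed"])
    hits = sum(1 for c in itertools.combinations(universe, 5)
               if len(set(c) & tags["tag"]) >= obs)
    total = 15504  # C(20, 5)
    assert df.loc["tag", "pvalue"] == pytest.approx(hits / total, rel=1e-9)


def test_fold_enrichment_fully_contained_cohort():
    universe = [f"g{i}" for i in range(100)]
    tags = {"t": set(universe[:10])}
    df = fold_enrichment(universe[:5], tags, 100)
    assert df["fold_enrichment"].iloc[0] == pytest.approx(10.0)


@pytest.mark.parametrize("seq, expected", [
    ("ATAT", 1.0), ("GCGC", 0.0), ("ATGC", 0.5), ("ATNN", 1.0),
])
def test_at_richness(seq, expected):
    assert at_richness({"g": seq})["g"] == pytest.approx(expected)


def test_at_richness_empty_sequence_undefined():
    assert np.isnan(at_richness({"g": ""})["g"])


def _toy_annotation(genes_rows, terminators=None, operons=None):
    genes = pd.DataFrame(genes_rows, columns=["gene_id", "strand", "tss",
                                              "left", "right"])
    genes["function_tag"] = "other"
    genes["fitness"] = 1.0
    genes["in_yfp_library"] = False
    genes["expression_level"] = 1.0
    return GenomeAnnotation(
        genes=genes, operons=operons or [],
        tf_edges=pd.DataFrame(columns=["regulator", "target"]),
        terminators=pd.DataFrame(terminators or [],
                                 columns=["position", "strand"]),
        promoter_sequences={})


class TestPairedPromoters:
    def test_divergent_pair_found(self):
        ann = _toy_annotation([("a", "-", 5000, 3900, 4800),
                               ("b", "+", 6000, 6200, 7100)])
        pairs = find_paired_promoters(ann)
        assert len(pairs) == 1
        assert pairs[0].geometry == "divergent"
        assert pairs[0].distance == 1000

    def test_distance_rule_is_strict(self):
        ann = _toy_annotation([("a", "-", 5000, 3900, 4800),
                               ("b", "+", 6600, 6800, 7700)])
        assert find_paired_promoters(ann) == []
        ann2 = _toy_annotation([("a", "-", 5000, 3900, 4800),
                                ("b", "+", 6500, 6700, 7600)])
        assert find_paired_promoters(ann2) == []  # exactly 1500 excluded

    def test_intervening_gene_body_blocks_pair(self):
        ann = _toy_annotation([("a", "-", 5000, 3900, 4800),
                               ("b", "+", 6000, 6200, 7100),
                               ("c", "+", 9000, 5300, 5700)])
        pairs = find_paired_promoters(ann)
        assert all({p.gene_a, p.gene_b} != {"a", "b"} for p in pairs)

    def test_intervening_terminator_blocks_pair(self):
        ann = _toy_annotation([("a", "-", 5000, 3900, 4800),
                               ("b", "+", 6000, 6200, 7100)],
                              terminators=[(5500, "+")])
        assert find_paired_promoters(ann) == []

    def test_convergent_and_tandem_geometries(self):
        conv = _toy_annotation([("a", "+", 5000, 5200, 5500),
                                ("b", "-", 6200, 5650, 6000)])
        assert [p.geometry for p in find_paired_promoters(conv)] == ["convergent"]
        tan = _toy_annotation([("a", "+", 5000, 5150, 5700),
                               ("b", "+", 5900, 6100, 6600)])
        assert [p.geometry for p in find_paired_promoters(tan)] == ["tandem"]


class TestOperonPairs:
    def test_planted_coupling_detected(self):
        spec = SynthSpec(seed=30, operon_coupling_fraction=1.0,
                         coupling_noise_sd=0.1)
        ann = generate_annotation(spec)
        lfc = generate_lfc_tables(spec, ann)
        csr = call_csr(lfc_slice(lfc, "CS", 20), lfc_slice(lfc, "CTRL", 20))
        res = operon_pair_analysis(csr, ann, lfc_slice(lfc, "CS", 20),
                                   n_null=200, seed=1)
        assert res.slope > 0
        assert res.slope_p < 0.01
        # planted coupling separates the real slope from the random-pairing null
        assert res.slope > np.quantile(res.null_slopes, 0.95)
        assert res.ancova_p < 0.05

    def test_uncoupled_data_indistinguishable_from_null(self):
        spec = SynthSpec(seed=31, operon_coupling_fraction=0.0)
        ann = generate_annotation(spec)
        lfc = generate_lfc_tables(spec, ann)
        csr = call_csr(lfc_slice(lfc, "CS", 20), lfc_slice(lfc, "CTRL", 20))
        res = operon_pair_analysis(csr, ann, lfc_slice(lfc, "CS", 20),
                                   n_null=200, seed=1)
        lo, hi = np.quantile(res.null_slopes, [0.025, 0.975])
        assert lo <= res.slope <= hi

    def test_no_multi_csr_operons_reports_empty(self):
        ann = _toy_annotation([("a", "+", 100, 200, 800),
                               ("b", "+", 2000, 2100, 2900)],
                              operons=[["a"], ["b"]])
        from coldshock.classify import CohortResult
        res = operon_pair_analysis(CohortResult(genes={"a", "b"}), ann,
                                   _table([("a", -1.0, 0.01), ("b", -1.0, 0.01)]),
                                   n_null=10)
        assert res.pairs.empty
        assert "no operon" in res.status


class TestTfPropagation:
    def test_planted_propagation_detected_and_destroyed_by_shuffling(self):
        spec = SynthSpec(seed=32, n_genes=600, tf_fraction=0.08,
                         tf_out_degree=5)
        ann = generate_annotation(spec)
        lfc = generate_lfc_tables(spec, ann)
        non_csr = set(ann.genes.loc[~ann.genes.planted_csr, "gene_id"])
        res = tf_propagation(ann.tf_edges, lfc_slice(lfc, "CS", 20),
                             lfc_slice(lfc, "CS", 80), target_filter=non_csr)
        assert res["r"] > 0.3
        assert res["p"] < 0.01
        rng = np.random.default_rng(0)
        shuffled = ann.tf_edges.copy()
        shuffled["target"] = rng.permutation(shuffled["target"].to_numpy())
        res_sh = tf_propagation(shuffled, lfc_slice(lfc, "CS", 20),
                                lfc_slice(lfc, "CS", 80), target_filter=non_csr)
        assert res_sh["r"] < res["r"] / 2

    def test_too_few_edges_rejected(self):
        edges = pd.DataFrame({"regulator": ["a"], "target": ["b"]})
        with pytest.raises(ValueError):
            tf_propagation(edges, _table([("a", 1.0, 0.01)]),
                           _table([("b", 1.0, 0.01)]))


class TestFitnessVariability:
    def test_identical_fitness_gives_zero_cv2(self):
        ann = _toy_annotation([(f"g{i}", "+", 100 + i * 2000, 200 + i * 2000,
                                800 + i * 2000) for i in range(10)])
        res = fitness_variability([f"g{i}" for i in range(5)], ann, n_null=50)
        assert res.cohort_cv2 == pytest.approx(0.0)

    @pytest.mark.parametrize("match", ["size_only", "size_and_function"])
    def test_planted_low_variability_cohort_detected(self, match):
        detected = 0
        seeds = range(10)
        for seed in seeds:
            spec = SynthSpec(seed=seed, csr_fitness_var_factor=0.4)
            ann = generate_annotation(spec)
            cohort = ann.genes.loc[ann.genes.planted_csr, "gene_id"]
            res = fitness_variability(cohort, ann, n_null=400, match=match,
                                      seed=seed)
            detected += res.percentile < 0.05
        assert detected >= 8


def test_select_reporters_thresholds():
    genes = pd.DataFrame({
        "gene_id": ["a", "b", "c", "d"],
        "strand": "+", "tss": [100, 2100, 4100, 6100],
        "left": [200, 2200, 4200, 6200], "right": [800, 2800, 4800, 6800],
        "function_tag": "other", "fitness": 1.0,
        "in_yfp_library": [True, True, False, True],
        "expression_level": [100.0, 100.0, 100.0, 0.1],
    })
    ann = GenomeAnnotation(genes=genes, operons=[],
                           tf_edges=pd.DataFrame(columns=["regulator", "target"]),
                           terminators=pd.DataFrame(columns=["position", "strand"]),
                           promoter_sequences={})
    from coldshock.classify import CohortResult
    csr = CohortResult(genes={"a", "b", "c", "d"})
    cs = _table([("a", -0.5, 0.01), ("b", -0.23, 0.01), ("c", -0.5, 0.01),
                 ("d", -0.5, 0.01)])
    result = select_reporters(csr, ann, cs, expression_percentile=10.0)
    assert "a" in result.genes
    assert "b" not in result.genes  # LFC exactly at -0.23 -> strict exclusion
    assert "c" not in result.genes  # not in YFP library
    assert "d" not in result.genes  # low expression


def test_at_lfc_correlation_runs_on_synthetic_data():
    spec = SynthSpec(seed=33)
    ann = generate_annotation(spec)
    lfc = generate_lfc_tables(spec, ann)
    res = at_lfc_correlation(at_richness(ann.promoter_sequences),
                             lfc_slice(lfc, "CS", 20))
    assert -1 <= res["r"] <= 1
    assert res["n"] > 100
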