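"""Training sets, validation, genome-wide screening, conservation crossing,
co-occurrence selection, and pathway enrichment."""

import numpy as np
import pandas as pd
import pytest

from ppmscreen.errors import ConfigError
from ppmscreen.ppm_model import PPMDefinition, Tier
from ppmscreen.screen import (
    OrthologMap,
    PathwayGeneSet,
    ScreenHit,
    build_training_sets,
    conserved_intersection,
    cooccurrence_select,
    pathway_enrichment,
    validate_ppm,
)
from ppmscreen.stats import round_half_up

from conftest import make_window


def de_frame(fdrs):
    return pd.DataFrame(
        {
            "gene_symbol": [f"G{i}" for i in range(len(fdrs))],
            "fold_change": [1.5] * len(fdrs),
            "direction": ["up"] * len(fdrs),
            "fdr": fdrs,
        }
    )


def ppm_window(gene, tid="T1"):
    return make_window([(50, "CAAGTG"), (160, "CACTTG")], gene=gene, tids=(tid,))


def ls_window(gene, tid="T1"):
    return make_window([(50, "CAAGTG"), (160, "CAAG")], gene=gene, tids=(tid,))


def bg_window(gene, tid="T1"):
    return make_window([], gene=gene, tids=(tid,))


class TestTrainingSets:
    def test_positive_set_is_the_confident_stratum(self):
        de = de_frame([0.001] * 30 + [0.05] * 20 + [0.5] * 50)
        universe = list(de["gene_symbol"]) + [f"U{i}" for i in range(100)]
        sets = build_training_sets(de, universe, n_neg=60, seed=1)
        assert len(sets.positive) == 30
        assert len(sets.negative) == 60
        assert not set(sets.positive) & set(sets.negative)

    def test_seed_determinism(self):
        de = de_frame([0.001] * 5 + [0.5] * 45)
        universe = list(de["gene_symbol"]) + [f"U{i}" for i in range(200)]
        a = build_training_sets(de, universe, n_neg=100, seed=7)
        b = build_training_sets(de, universe, n_neg=100, seed=7)
        assert a.positive == b.positive and a.negative == b.negative

    def test_insufficient_universe(self):
        de = de_frame([0.001] * 5 + [0.5] * 5)
        with pytest.raises(ConfigError, match="negative set"):
            build_training_sets(de, list(de["gene_symbol"]), n_neg=10, seed=0)


class TestValidatePPM:
    def test_published_shape_counts_reproduce_table_surface(self):
        pos = [ppm_window(f"P{i}") for i in range(3)] + [bg_window(f"P{i}") for i in range(3, 30)]
        neg = [ppm_window(f"N{i}") for i in range(9)] + [bg_window(f"N{i}") for i in range(9, 2000)]
        d = validate_ppm(pos, neg).to_dict()["PPM"]
        assert (d["pos_hit"], d["neg_hit"]) == (3, 9)
        assert d["fold_enrichment"] == 22.2
        assert d["sensitivity_pct"] == 10.0
        assert d["specificity_pct"] == 99.6
        assert d["fisher_p"] == pytest.approx(6e-4, rel=0.05)

    def test_identical_sets_give_null_result(self):
        wins = [ppm_window(f"G{i}") for i in range(4)] + [bg_window(f"G{i}") for i in range(4, 8)]
        d = validate_ppm(wins, wins).to_dict()["PPM"]
        assert d["fold_enrichment"] == 1.0
        assert d["fisher_p"] == pytest.approx(1.0)

    def test_sensitivity_non_decreasing_across_tiers(self):
        pos = (
            [ppm_window(f"P{i}") for i in range(2)]
            + [ls_window(f"P{i}") for i in range(2, 5)]
            + [bg_window(f"P{i}") for i in range(5, 10)]
        )
        neg = [bg_window(f"N{i}") for i in range(10)]
        d = validate_ppm(pos, neg).to_dict()
        sens = [d[t]["sensitivity_pct"] for t in ("PPM", "LS-PPM", "VLS-PPM")]
        assert sens == sorted(sens)

    def test_gene_counts_any_window_semantics(self):
        # a gene with one fitting and one background alternative promoter fits
        pos = [ppm_window("P0", "T1"), bg_window("P0", "T2")]
        neg = [bg_window(f"N{i}") for i in range(5)]
        assert validate_ppm(pos, neg).to_dict()["PPM"]["pos_hit"] == 1

    def test_empty_set_rejected(self):
        with pytest.raises(ConfigError):
            validate_ppm([], [bg_window("N")])


class TestScreenGenome:
    def test_planted_genes_are_retrieved(self):
        wins = [ppm_window("A"), ppm_window("B")] + [bg_window(f"C{i}") for i in range(8)]
        hits = screen_genome_sorted(wins)
        assert [h.gene_symbol for h in hits] == ["A", "B"]

    def test_alternative_promoters_report_best_window(self):
        multi = make_window(
            [(20, "CAAGTG"), (120, "CAAGTG"), (240, "CAAGTG")], gene="A", tids=("T2",)
        )
        wins = [ppm_window("A", "T1"), multi, bg_window("B")]
        hits = screen_genome_sorted(wins)
        assert len(hits) == 1
        assert hits[0].transcript_ids == ("T2",)
        assert hits[0].canonical_site_count == 3
        assert hits[0].admissible_pair_count == 2

    def test_hit_sets_monotone_in_tier(self):
        wins = (
            [ppm_window(f"A{i}") for i in range(3)]
            + [ls_window(f"B{i}") for i in range(3)]
            + [bg_window(f"C{i}") for i in range(4)]
        )
        by_tier = {
            tier: {h.gene_symbol for h in screen_genome_sorted(wins, tier)}
            for tier in (Tier.PPM, Tier.LS_PPM, Tier.VLS_PPM)
        }
        assert by_tier[Tier.PPM] <= by_tier[Tier.LS_PPM] <= by_tier[Tier.VLS_PPM]


def screen_genome_sorted(wins, tier=Tier.PPM):
    from ppmscreen.screen import screen_genome

    return screen_genome(wins, PPMDefinition(tier=tier))


def hit(gene, pairs, sites):
    return ScreenHit(
        gene_symbol=gene,
        transcript_ids=("T",),
        fits={t: True for t in Tier},
        canonical_site_count=sites,
        admissible_pair_count=pairs,
    )


class TestConservedIntersection:
    def test_example_crossing(self):
        hits_a = [hit("A", 1, 2), hit("B", 1, 2)]
        hits_b = [hit("A'", 1, 2), hit("C'", 1, 2)]
        ortho = OrthologMap([("A", "A'"), ("B", "B'")])
        assert conserved_intersection(hits_a, hits_b, ortho) == [("A", "A'")]

    def test_disjoint_hits_empty(self):
        ortho = OrthologMap([("A", "A'")])
        assert conserved_intersection([hit("B", 1, 2)], [hit("C'", 1, 2)], ortho) == []

    def test_symmetry_under_species_swap(self):
        hits_a = [hit(g, 1, 2) for g in "ABC"]
        hits_b = [hit(g + "'", 1, 2) for g in "BCD"]
        ortho = OrthologMap([(g, g + "'") for g in "ABCD"])
        forward = conserved_intersection(hits_a, hits_b, ortho)
        inverted = OrthologMap([(b, a) for a, b in ortho.pairs])
        backward = conserved_intersection(hits_b, hits_a, inverted)
        assert sorted((a, b) for a, b in forward) == sorted((b, a) for a, b in backward)


class TestCooccurrenceSelect:
    def test_selects_multi_pair_genes_ranked(self):
        hits = [hit("A", 1, 2), hit("B", 2, 3), hit("C", 2, 3), hit("D", 3, 4)]
        assert [h.gene_symbol for h in cooccurrence_select(hits)] == ["D", "B", "C"]

    def test_single_pair_hits_are_never_selected(self):
        assert cooccurrence_select([hit("A", 1, 2), hit("B", 1, 3)]) == []

    def test_tie_broken_by_site_count_then_symbol(self):
        hits = [hit("Z", 2, 3), hit("A", 2, 3), hit("M", 2, 4)]
        assert [h.gene_symbol for h in cooccurrence_select(hits)] == ["M", "A", "Z"]

    def test_selection_is_subset_of_screen(self):
        hits = [hit("A", 2, 3), hit("B", 1, 2)]
        assert {h.gene_symbol for h in cooccurrence_select(hits)} <= \
            {h.gene_symbol for h in hits}


class TestPathwayEnrichment:
    def test_reconstructed_axon_guidance_shape(self):
        pathway = PathwayGeneSet(
            "pwy", frozenset({"A", "B", "C"} | {f"p{i}" for i in range(132)}), 25504
        )
        selected = ["A", "B", "C"] + [f"x{i}" for i in range(7)]
        result = pathway_enrichment(selected, pathway)
        assert round_half_up(result.fold) == 56.7
        assert result.p_value < 1e-4

    def test_uniform_selection_has_unit_expected_fold(self, rng):
        members = frozenset(f"g{i}" for i in range(0, 1000))
        pathway = PathwayGeneSet("pwy", members, universe_size=10000)
        universe = [f"g{i}" for i in range(10000)]
        folds = []
        for _ in range(40):
            sel = [universe[i] for i in rng.choice(10000, size=200, replace=False)]
            folds.append(pathway_enrichment(sel, pathway).fold)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.15)

    def test_no_pathway_hits_gives_zero_fold(self):
        pathway = PathwayGeneSet("pwy", frozenset({"A", "B"}), 1000)
        assert pathway_enrichment(["X", "Y"], pathway).fold == 0.0

    def test_empty_selection_rejected(self):
        pathway = PathwayGeneSet("pwy", frozenset({"A"}), 1000)
        with pytest.raises(ConfigError):
            pathway_enrichment([], pathway)
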