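"""Expression-based candidate filters and intersection."""

import numpy as np
import pandas as pd
import pytest

from metaqtl_forge.expression import (ExpressionMatrix, de_across_interval,
                                      filter_expressed_atlas,
                                      filter_fpkm_expressed,
                                      find_onset_interval, go_slim_filter,
                                      intersect_candidates,
                                      select_transcriptomic_candidates)
from metaqtl_forge.models import CandidateGene, GeneModel


def tiny_matrix(values_by_gene, years=(2012,), n_tp=4, n_rep=3):
    """values_by_gene: gene -> (year, tp) -> list of replicate FPKM."""
    rows, cols = [], {}
    for year in years:
        for tp in range(1, n_tp + 1):
            for rep in range(1, n_rep + 1):
                name = f"s{year}_t{tp}_r{rep}"
                rows.append({"sample": name, "year": year,
                             "timepoint_order": tp,
                             "days_before_veraison": 10 * (n_tp - tp),
                             "replicate": rep})
                cols[name] = [values_by_gene[g][(year, tp)][rep - 1]
                              for g in values_by_gene]
    values = pd.DataFrame(cols, index=list(values_by_gene))
    return ExpressionMatrix(values=values, samples=pd.DataFrame(rows))


class TestAtlasFilter:
    CALLS = pd.DataFrame(
        {"berry": [True, False, False], "rachis": [False, True, False],
         "seed": [False, False, False], "leaf": [False, False, True]},
        index=["g_berry", "g_rachis", "g_leaf"])

    def test_leaf_only_gene_excluded(self):
        out = filter_expressed_atlas(["g_leaf"], self.CALLS)
        assert out == set()

    def test_rachis_gene_retained(self):
        out = filter_expressed_atlas(["g_rachis", "g_leaf"], self.CALLS)
        assert out == {"g_rachis"}

    def test_empty_organ_set_rejected(self):
        with pytest.raises(ValueError):
            filter_expressed_atlas(["g_berry"], self.CALLS, organs=[])

    def test_planted_silent_genes_excluded_exactly(self, bundle):
        genes = [g.gene_id for g in bundle.genes]
        kept = filter_expressed_atlas(genes, bundle.atlas_calls)
        assert set(genes) - kept == set(bundle.truth.atlas_fail_genes)
        assert len(kept) == len(genes) - len(bundle.truth.atlas_fail_genes)


class TestFPKMFilter:
    def test_uniformly_low_gene_removed(self):
        mat = tiny_matrix({"g": {(2012, t): [0.5, 0.5, 0.5]
                                 for t in range(1, 5)}})
        assert filter_fpkm_expressed(mat) == set()

    def test_two_replicates_at_threshold_retained(self):
        vals = {("2012", t): [0.0, 0.0, 0.0] for t in range(1, 5)}
        vals = {(2012, t): [0.0, 0.0, 0.0] for t in range(1, 5)}
        vals[(2012, 2)] = [1.2, 1.1, 0.0]
        mat = tiny_matrix({"g": vals})
        assert filter_fpkm_expressed(mat) == {"g"}

    def test_matches_bruteforce_quantifier(self):
        rng = np.random.default_rng(41)
        genes = {f"g{i}": {(2012, t): list(rng.uniform(0, 3, 3))
                           for t in range(1, 5)} for i in range(30)}
        mat = tiny_matrix(genes)
        got = filter_fpkm_expressed(mat, threshold=1.0, min_reps=2)
        exp = {g for g, tbl in genes.items()
               if any(sum(v >= 1.0 for v in reps) >= 2
                      for reps in tbl.values())}
        assert got == exp


class TestDEAcrossInterval:
    def test_flat_means_not_de(self):
        mat = tiny_matrix({"g": {(2012, 1): [2, 2, 2], (2012, 2): [2, 2, 2],
                                 (2012, 3): [2, 2, 2], (2012, 4): [2, 2, 2]}})
        assert not de_across_interval(mat, "g", (1, 2), 2012)

    def test_fourfold_with_pseudocount_is_de(self):
        mat = tiny_matrix({"g": {(2012, 1): [1, 1, 1], (2012, 2): [7, 7, 7],
                                 (2012, 3): [7, 7, 7], (2012, 4): [7, 7, 7]}})
        assert de_across_interval(mat, "g", (1, 2), 2012)  # log2(8/2) = 2

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(43)
        genes = {f"g{i}": {(2012, t): list(rng.uniform(0, 20, 3))
                           for t in range(1, 5)} for i in range(25)}
        mat = tiny_matrix(genes)
        for lo, hi in [(0.5, 1.0), (1.0, 2.0)]:
            sel_lo = {g for g in genes
                      if de_across_interval(mat, g, (1, 2), 2012, lo)}
            sel_hi = {g for g in genes
                      if de_across_interval(mat, g, (1, 2), 2012, hi)}
            assert sel_hi <= sel_lo


class TestOnsetInterval:
    def test_planted_jump_recovered(self):
        genes = {}
        for i in range(5):
            # flat at 2.0, then a jump between time points 3 and 4
            genes[f"b{i}"] = {(2012, t): [2.0] * 3 if t <= 3 else [20.0] * 3
                              for t in range(1, 6)}
        mat = tiny_matrix(genes, n_tp=5)
        assert find_onset_interval(mat, list(genes), 2012) == (3, 4)

    def test_tie_resolves_to_earliest_pair(self):
        genes = {
            "b1": {(2012, 1): [1, 1, 1], (2012, 2): [9, 9, 9],
                   (2012, 3): [9, 9, 9], (2012, 4): [9, 9, 9]},
            "b2": {(2012, 1): [9, 9, 9], (2012, 2): [9, 9, 9],
                   (2012, 3): [1, 1, 1], (2012, 4): [1, 1, 1]},
        }
        mat = tiny_matrix(genes)
        assert find_onset_interval(mat, ["b1", "b2"], 2012) == (1, 2)

    def test_empty_biomarker_list_rejected(self):
        mat = tiny_matrix({"g": {(2012, t): [1, 1, 1] for t in range(1, 5)}})
        with pytest.raises(ValueError):
            find_onset_interval(mat, [], 2012)

    def test_planted_transition_recovered_in_all_years(self, bundle):
        mat = ExpressionMatrix(values=bundle.fpkm, samples=bundle.samples)
        for year in bundle.cfg.years:
            got = find_onset_interval(mat, bundle.biomarkers, year)
            assert got == bundle.truth.transition_interval[year]


class TestCandidateSelection:
    def _mat(self):
        def series(step_years):
            out = {}
            for year in (2012, 2013, 2014):
                for t in range(1, 5):
                    base = 2.0
                    if year in step_years and t >= 3:
                        base = 16.0
                    out[(year, t)] = [base] * 3
            return out

        genes = {"two_years": series({2012, 2014}),
                 "one_year": series({2013}),
                 "biom": series({2012, 2013, 2014}),
                 "flat": series(set())}
        return tiny_matrix(genes, years=(2012, 2013, 2014))

    def test_two_year_gene_selected_one_year_gene_not(self):
        mat = self._mat()
        got = select_transcriptomic_candidates(mat, ["biom"], [])
        assert "two_years" in got and "biom" in got
        assert "one_year" not in got and "flat" not in got

    def test_de_list_always_included(self):
        mat = self._mat()
        got = select_transcriptomic_candidates(mat, ["biom"], ["flat"])
        assert "flat" in got


class TestIntersection:
    G1 = GeneModel("g1", "chr1", 10, 20)
    G2 = GeneModel("g2", "chr1", 30, 40)

    def test_disjoint_sets_empty(self):
        out = intersect_candidates({"mq1": [self.G1]}, {"zzz"})
        assert out == []

    def test_positional_subset_of_transcriptomic(self):
        out = intersect_candidates({"mq1": [self.G1, self.G2]}, {"g1", "g2"})
        assert sorted(c.gene_id for c in out) == ["g1", "g2"]
        assert all(c.metaqtl == "mq1" for c in out)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            intersect_candidates({}, {"g1"})


class TestGoSlim:
    TABLE = pd.DataFrame({"gene": ["g1", "g2", "g3"],
                          "go": ["GO:0003700", "GO:0008150", "badformat"]})

    def _cands(self):
        return [CandidateGene(gene_id=g, metaqtl="mq1")
                for g in ("g1", "g2", "g3")]

    def test_slim_accession_flagged(self):
        out = go_slim_filter(self._cands(), self.TABLE)
        assert [c.gene_id for c in out] == ["g1"]
        assert out[0].regulatory

    def test_non_slim_accession_not_flagged(self):
        cands = self._cands()
        go_slim_filter(cands, self.TABLE)
        assert not cands[1].regulatory

    def test_planted_regulatory_subset_flagged_exactly(self, bundle):
        cands = [CandidateGene(gene_id=g.gene_id, metaqtl="mq")
                 for g in bundle.genes]
        out = go_slim_filter(cands, bundle.go_table)
        assert {c.gene_id for c in out} == set(bundle.truth.regulatory_genes)
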