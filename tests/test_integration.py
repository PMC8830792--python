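"""Dual-evidence ledger and Fisher overlap analyses."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tfeqtl as tq
from tfeqtl.integration import (
    build_dual_evidence,
    fisher_overlap,
    gwas_coloc_overlap,
    gxe_overlap,
    ld_r2,
    regulon_enrichment,
)


def _within_row(tf, gene, tissue, variant="v1", passed=True):
    return {"tf": tf, "gene": gene, "tissue": tissue, "variant": variant,
            "pass": passed}


def _cross_row(tf, gene, variant="v1", passed=True, mode="expression"):
    return {"tf": tf, "gene": gene, "variant": variant, "mode": mode,
            "pass": passed}


class TestDualEvidence:
    def test_two_tissues_is_dual(self):
        led = build_dual_evidence(
            [pd.DataFrame([_within_row("F", "g", "A")]),
             pd.DataFrame([_within_row("F", "g", "B")])],
        )
        assert bool(led.iloc[0]["dual_evidence"])

    def test_cross_only_is_not_dual(self):
        led = build_dual_evidence([], pd.DataFrame([_cross_row("F", "g")]))
        assert not bool(led.iloc[0]["dual_evidence"])

    def test_cross_plus_one_tissue_is_dual(self):
        led = build_dual_evidence(
            [pd.DataFrame([_within_row("F", "g", "A")])],
            pd.DataFrame([_cross_row("F", "g")]),
        )
        assert bool(led.iloc[0]["dual_evidence"])

    def test_protein_mode_never_counts_as_evidence(self):
        led = build_dual_evidence(
            [pd.DataFrame([_within_row("F", "g", "A")])],
            pd.DataFrame([_cross_row("F", "g", mode="protein")]),
        )
        assert not bool(led.iloc[0]["dual_evidence"])

    def test_idempotent_and_order_independent(self):
        tabs = [pd.DataFrame([_within_row("F", "g", "A")]),
                pd.DataFrame([_within_row("F", "g", "B")]),
                pd.DataFrame([_within_row("G", "h", "A")])]
        cross = pd.DataFrame([_cross_row("G", "h")])
        led1 = build_dual_evidence(tabs, cross)
        led2 = build_dual_evidence(tabs[::-1], cross)
        led3 = build_dual_evidence(tabs + tabs, cross)  # duplicated inputs
        pd.testing.assert_frame_equal(led1, led2)
        pd.testing.assert_frame_equal(led1, led3)

    def test_failed_rows_ignored(self):
        led = build_dual_evidence(
            [pd.DataFrame([_within_row("F", "g", "A", passed=False)])],
        )
        assert len(led) == 0


class TestFisherOverlap:
    def test_disjoint_sets_covering_universe(self):
        t = fisher_overlap({1, 2}, {3, 4}, {1, 2, 3, 4})
        assert t.odds_ratio == 0.0 and t.a == 0

    def test_balanced_table_is_null(self):
        uni = set(range(40))
        t = fisher_overlap(set(range(20)), set(range(10, 30)), uni)
        assert t.table == [[10, 10], [10, 10]]
        assert t.odds_ratio == pytest.approx(1.0)
        assert t.p == pytest.approx(1.0)

    def test_toy_table_odds_ratio_and_hypergeom_p(self):
        # a=20, b=10, c=10, d=60 -> OR = (20*60)/(10*10) = 12
        uni = set(range(100))
        A = set(range(30))
        B = set(range(20)) | set(range(30, 40))
        t = fisher_overlap(A, B, uni)
        assert t.table == [[20, 10], [10, 60]]
        assert t.odds_ratio == pytest.approx(12.0)
        assert t.p == pytest.approx(stats.fisher_exact([[20, 10], [10, 60]])[1])

    def test_two_sided_p_equals_enumeration_for_small_margins(self):
        def oracle(a, b, c, d):
            row1, col1, n = a + b, a + c, a + b + c + d
            lo, hi = max(0, row1 + col1 - n), min(row1, col1)
            probs = [stats.hypergeom.pmf(k, n, row1, col1) for k in range(lo, hi + 1)]
            p_obs = stats.hypergeom.pmf(a, n, row1, col1)
            return sum(p for p in probs if p <= p_obs * (1 + 1e-9))

        rng = np.random.default_rng(0)
        # exhaustive over tiny tables plus random tables with margins <= 30
        tables = [(a, b, c, d) for a in range(5) for b in range(5)
                  for c in range(5) for d in range(5) if a + b + c + d > 0]
        for _ in range(300):
            tables.append(tuple(int(x) for x in rng.integers(0, 16, size=4)))
        for a, b, c, d in tables:
            if a + b + c + d == 0:
                continue
            uni = set(range(a + b + c + d))
            A = set(range(a + b))
            B = set(range(a)) | set(range(a + b, a + b + c))
            t = fisher_overlap(A, B, uni)
            assert t.p == pytest.approx(oracle(a, b, c, d), abs=1e-9), (a, b, c, d)

    def test_members_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap({1}, {2}, {2})
        with pytest.raises(ValueError):
            fisher_overlap(set(), set(), set())


class TestRegulons:
    def _ledger(self):
        return pd.DataFrame(
            [{"tf": "F", "gene": "g1", "sources": "A,B", "n_tissues": 2,
              "cross_tissue": False, "variants": "v1", "dual_evidence": True},
             {"tf": "G", "gene": "g2", "sources": "A,cross-expression",
              "n_tissues": 1, "cross_tissue": True, "variants": "v2",
              "dual_evidence": True}],
        )

    def test_any_regulon_is_union(self):
        regs = {"curated": {"F": {"g1"}}, "chipseq": {"F": {"g3"}},
                "motif": {"F": set()}, "coexpression": {"F": {"g1", "g4"}}}
        uni = {f"g{i}" for i in range(1, 8)}
        per, pooled = regulon_enrichment(self._ledger(), regs, uni)
        any_rows = per[per["regulon_type"] == "any"]
        assert set(any_rows["tf"]) == {"F"}
        a, b = int(any_rows.iloc[0]["a"]), int(any_rows.iloc[0]["b"])
        assert a + b == 1  # F has one dual-evidence gene
        assert a == 1      # g1 is in the union

    def test_pooled_cells_are_sums_over_tfs(self):
        # per-TF tables are degenerate (one gene each) but their summed cells
        # are not, so the pooled OR is finite and equal to the cell arithmetic
        regs = {"curated": {"F": {"g1", "g3"}, "G": {"g5"}}}
        uni = {f"g{i}" for i in range(1, 8)}
        per, pooled = regulon_enrichment(self._ledger(), regs, uni)
        cur = per[per["regulon_type"] == "curated"]
        pl = pooled[pooled["regulon_type"] == "curated"].iloc[0]
        for cell in "abcd":
            assert pl[cell] == cur[cell].sum()
        # pooled OR equals the OR of the summed cells
        assert pl["odds_ratio"] == pytest.approx(
            (pl["a"] * pl["d"]) / (pl["b"] * pl["c"])
        )

    def test_tf_without_regulon_skipped(self):
        regs = {"curated": {"F": {"g1"}}}
        per, _ = regulon_enrichment(self._ledger(), regs, {"g1", "g2", "g3"})
        assert "G" not in set(per["tf"])


class TestLdR2:
    def test_identical_and_flipped_dosages(self):
        d = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        assert ld_r2(d, d) == pytest.approx(1.0)
        assert ld_r2(d, 2 - d) == pytest.approx(1.0)

    def test_linear_recoding_invariance(self):
        d = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        assert ld_r2(d, 3.0 * d - 1.0) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.binomial(2, 0.4, size=10_000).astype(float)
        b = rng.binomial(2, 0.4, size=10_000).astype(float)
        assert ld_r2(a, b) < 0.01

    def test_monomorphic_is_undefined(self):
        assert np.isnan(ld_r2([1, 1, 1], [0, 1, 2]))

    def test_missing_dropped_pairwise(self):
        a = np.array([0, 1, 2, np.nan])
        b = np.array([0, 1, 2, 0.0])
        assert ld_r2(a, b) == pytest.approx(1.0)


class TestGxEOverlap:
    def test_empty_gxe_set(self):
        t = gxe_overlap({"g1"}, set(), {"g1", "g2"})
        assert t.a == 0 and t.odds_ratio == 0.0

    def test_degenerate_universe_flagged(self):
        t = gxe_overlap({"g1"}, {"g2"}, {"g1", "g2"})
        assert t.d == 0 and t.flagged

    def test_toy_odds_ratio(self):
        # universe 1000, |A| = 100, |B| = 50, overlap 20 -> OR = 7.25
        uni = set(range(1000))
        A = set(range(100))
        B = set(range(20)) | set(range(100, 130))
        t = gxe_overlap(A, B, uni)
        assert t.table == [[20, 80], [30, 870]]
        assert t.odds_ratio == pytest.approx((20 * 870) / (80 * 30))
        assert t.odds_ratio == pytest.approx(7.25)


class TestGwasColoc:
    def _setup(self):
        geno = tq.generate_genotypes(60, 4, 0.3, 0.4, ld_block_size=2, seed=2,
                                     flip_prob=0.0)
        vids = geno.variant_ids
        ledger = pd.DataFrame(
            [{"tf": "F", "gene": "g1", "sources": "A,B", "n_tissues": 2,
              "cross_tissue": False, "variants": vids[0], "dual_evidence": True},
             {"tf": "G", "gene": "g2", "sources": "A,cross-expression",
              "n_tissues": 1, "cross_tissue": True, "variants": vids[2],
              "dual_evidence": True}],
        )
        coloc = pd.DataFrame(
            [{"gene": "g1", "tissue": "A", "trait": "t", "rcp": 0.9,
              "lead_variant": vids[1]},     # same LD block as vids[0]: r2 = 1
             {"gene": "g2", "tissue": "A", "trait": "t", "rcp": 0.5,
              "lead_variant": vids[3]},     # rcp exactly at threshold
             {"gene": "g3", "tissue": "B", "trait": "t", "rcp": 0.8,
              "lead_variant": "missing_variant"}],
        )
        return geno, ledger, coloc

    def test_rcp_threshold_is_strict(self):
        geno, ledger, coloc = self._setup()
        genes = {"g1", "g2", "g3", "g4"}
        gene_t, pair_t, matches = gwas_coloc_overlap(
            ledger, coloc, geno, genes, tissue_universe={"A", "B"},
        )
        # the rcp = 0.5 row is excluded everywhere
        assert "g2" not in set(matches["gene"])
        assert gene_t.a == 1  # only g1 counts as colocalized TF-eQTL gene

    def test_r2_filter_and_strictness(self):
        geno, ledger, coloc = self._setup()
        _, _, matches = gwas_coloc_overlap(
            ledger, coloc, geno, {"g1", "g2", "g3"}, tissue_universe={"A", "B"},
        )
        m = matches[matches["gene"] == "g1"].iloc[0]
        assert m["r2"] == pytest.approx(1.0) and bool(m["kept"])
        # a boundary r2 equal to the threshold is excluded (strict >)
        _, _, strict = gwas_coloc_overlap(
            ledger, coloc, geno, {"g1", "g2", "g3"}, tissue_universe={"A", "B"},
            r2_min=1.0,
        )
        assert not bool(strict[strict["gene"] == "g1"].iloc[0]["kept"])

    def test_missing_lead_variant_flagged_not_dropped(self):
        geno, ledger, coloc = self._setup()
        ledger2 = pd.concat(
            [ledger, pd.DataFrame([{"tf": "H", "gene": "g3", "sources": "B",
                                    "n_tissues": 1, "cross_tissue": False,
                                    "variants": geno.variant_ids[0],
                                    "dual_evidence": True}])],
            ignore_index=True,
        )
        _, _, matches = gwas_coloc_overlap(
            ledger2, coloc, geno, {"g1", "g2", "g3"}, tissue_universe={"A", "B"},
        )
        row = matches[matches["gene"] == "g3"].iloc[0]
        assert bool(row["unresolved"]) and np.isnan(row["r2"])

    def test_synthetic_overlap_counts_match_set_arithmetic(self, small_study, small_discovery):
        genes = set(small_discovery.candidates["gene"])
        coloc = small_study.coloc_table
        gene_t, _, _ = gwas_coloc_overlap(
            small_discovery.ledger, coloc, small_study.genotypes, genes,
            tissue_universe=set(small_study.tissue_names),
        )
        de_genes = {g for g in small_discovery.ledger.loc[
            small_discovery.ledger["dual_evidence"], "gene"]} & genes
        coloc_genes = set(coloc.loc[coloc["rcp"] > 0.5, "gene"]) & genes
        assert gene_t.a == len(de_genes & coloc_genes)
        assert gene_t.a + gene_t.b == len(de_genes)
        assert gene_t.a + gene_t.c == len(coloc_genes)
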