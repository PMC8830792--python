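"""Synthetic-cohort generator: occupancy model, genotypes, truth, writers."""
import numpy as np
import pandas as pd
import pytest

import tfeqtl as tq
from tfeqtl.io import load_study, write_study
from tfeqtl.synthetic import AFC_GRID
from tfeqtl.types import ModelKind, OccupancyModel, SimulationTruth


@pytest.fixture(scope="module")
def model() -> OccupancyModel:
    return OccupancyModel(basal_rate=1, max_rate=9, K_ref=10, K_alt=1)


class TestGenotypes:
    def test_dosage_codomain_and_maf_recorded(self):
        g = tq.generate_genotypes(4, 6, 0.45, 0.45, ld_block_size=1, seed=0)
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}
        assert list(g.variants.columns) == ["chrom", "pos", "ref", "alt", "maf"]
        assert np.allclose(g.variants["maf"], g.maf())

    def test_zero_flip_block_gives_identical_columns(self):
        g = tq.generate_genotypes(50, 2, 0.3, 0.3, ld_block_size=2, seed=1, flip_prob=0.0)
        assert np.array_equal(g.dosages[:, 0], g.dosages[:, 1])  # r^2 = 1

    def test_realized_maf_matches_binomial_sampling(self):
        # binomial oracle: per-variant allele freq has sd sqrt(0.3*0.7/1000) ~ 0.014,
        # so the mean realized MAF over 200 variants sits well inside 0.3 +/- 0.03
        g = tq.generate_genotypes(500, 200, 0.3, 0.3, ld_block_size=1, seed=2)
        assert abs(g.variants["maf"].mean() - 0.3) < 0.03

    @pytest.mark.parametrize("kwargs", [
        {"n_individuals": 1, "n_variants": 5},
        {"n_individuals": 10, "n_variants": 0},
        {"n_individuals": 10, "n_variants": 5, "maf_low": 0.0},
        {"n_individuals": 10, "n_variants": 5, "maf_low": 0.3, "maf_high": 0.2},
    ])
    def test_invalid_arguments(self, kwargs):
        defaults = dict(maf_low=0.1, maf_high=0.4)
        defaults.update(kwargs)
        with pytest.raises(ValueError):
            tq.generate_genotypes(**defaults)


class TestOccupancyModel:
    def test_hand_evaluated_outputs(self, model):
        # hom-ref: 2*(1 + 8*3/13); hom-alt: 2*(1 + 8*3/4); aFC = log2(7/2.84615)
        e = tq.simulate_expression([0, 2], model, [3.0, 3.0], noise_sd=0.0)
        assert e[0] == pytest.approx(2 * (1 + 8 * 3 / 13))
        assert e[1] == pytest.approx(14.0)
        assert float(model.log2_afc(3.0)) == pytest.approx(np.log2(7.0 / (1 + 8 * 3 / 13)), abs=1e-12)
        assert float(model.log2_afc(3.0)) == pytest.approx(1.299, abs=1e-3)

    def test_no_eqtl_at_zero_tf_or_saturation(self, model):
        for T in (0.0, 1e12):
            e = tq.simulate_expression([0, 1, 2], model, [T] * 3, noise_sd=0.0)
            assert np.allclose(e, e[0], rtol=1e-6)

    def test_afc_curve_unimodal_with_zero_limits(self, model):
        grid = np.logspace(-5, 6, 200)
        afc = model.log2_afc(grid)
        assert afc[0] == pytest.approx(0.0, abs=1e-3)
        assert afc[-1] == pytest.approx(0.0, abs=1e-3)
        d = np.diff(afc)
        # strictly rising then strictly falling: exactly one sign change
        sign_changes = np.sum(np.diff(np.sign(d)) != 0)
        assert sign_changes == 1
        assert afc.max() > 0.5

    def test_site_gain_models_are_monotone(self):
        # a gained site with the same affinity as the shared one yields a
        # monotone allelic fold change that saturates at a nonzero plateau
        for kind in (ModelKind.additive_site, ModelKind.multiplicative_site):
            m = OccupancyModel(basal_rate=1, max_rate=9, K_ref=10, K_alt=10, model_kind=kind)
            afc = m.log2_afc(np.logspace(-3, 4, 100))
            assert np.all(np.diff(afc) > -1e-12)
            assert afc[0] == pytest.approx(0.0, abs=1e-2)
            assert afc[-1] > 0.5

    def test_affinity_gain_raises_alt_output_at_intermediate_tf(self, model):
        assert model.allele_output(1.0, "alt") > model.allele_output(1.0, "ref")

    def test_invalid_model_and_noise(self):
        with pytest.raises(ValueError):
            OccupancyModel(basal_rate=2, max_rate=1)
        with pytest.raises(ValueError):
            OccupancyModel(K_ref=-1)
        with pytest.raises(ValueError):
            tq.simulate_expression([0], OccupancyModel(), [1.0], noise_sd=-0.1)
        with pytest.raises(ValueError):
            tq.simulate_expression([0], OccupancyModel(), [-1.0], noise_sd=0.0)


class TestGenerateStudy:
    def test_zero_fraction_gives_empty_truth(self):
        cfg = tq.ScenarioConfig(n_individuals=40, n_tissues=2, n_genes=10,
                                samples_per_tissue=30, truth_fraction=0.0)
        study = tq.generate_study(cfg, seed=3)
        assert study.truth.true_tf_eqtls == set()

    def test_fraction_sets_exact_truth_count(self):
        cfg = tq.ScenarioConfig(n_individuals=40, n_tissues=2, n_genes=100,
                                samples_per_tissue=30, truth_fraction=0.2)
        study = tq.generate_study(cfg, seed=4)
        assert len(study.truth.true_genes) == 20

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            tq.ScenarioConfig(truth_fraction=1.5)

    def test_same_seed_reproduces_study_exactly(self):
        cfg = tq.ScenarioConfig(n_individuals=40, n_tissues=3, n_genes=12,
                                samples_per_tissue=30)
        a = tq.generate_study(cfg, seed=5)
        b = tq.generate_study(cfg, seed=5)
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
        assert a.genome == b.genome
        assert a.truth.true_tf_eqtls == b.truth.true_tf_eqtls
        pd.testing.assert_frame_equal(a.credible_sets, b.credible_sets)
        pd.testing.assert_frame_equal(a.asb_table, b.asb_table)
        pd.testing.assert_frame_equal(a.allelic_counts, b.allelic_counts)
        for ta, tb in zip(a.tissues, b.tissues):
            pd.testing.assert_frame_equal(ta.tpm, tb.tpm)

    def test_sample_ids_consistent_and_truth_genes_everywhere(self, small_study):
        inds = set(small_study.genotypes.individuals)
        for tis in small_study.tissues:
            assert set(tis.samples) <= inds
            assert tis.covariates.index.equals(tis.tpm.columns)
            for gene in small_study.truth.true_genes:
                assert gene in tis.tpm.index

    def test_truth_variants_carry_concordant_annotation(self, small_study):
        from tfeqtl.filtering import iupac_to_patterns, motif_match, peak_overlap

        variants = small_study.genotypes.variants
        truth = sorted(small_study.truth.true_tf_eqtls)
        sub = variants.loc[[v for _, _, v in truth]]
        peak_sets = peak_overlap(sub, small_study.annotations)
        for tf, gene, vid in truth:
            assert tf in peak_sets[vid]
            pat = iupac_to_patterns(small_study.annotations.motifs[tf])
            row = variants.loc[vid]
            ref_m, alt_m = motif_match(
                (row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                small_study.fetch, pat,
            )
            assert ref_m or alt_m

    def test_planted_afc_curve_on_grid(self, small_study):
        for key, curve in small_study.truth.planted_afc_curve.items():
            assert set(curve) == set(AFC_GRID)
            assert curve[0.0] == 0.0


class TestKnockdownCounts:
    def _truth(self, model):
        key = ("TF00", "geneX", "varX")
        return SimulationTruth(
            true_tf_eqtls={key}, planted_afc_curve={}, confounds=[], seed=0,
            models={key: model},
        )

    def test_equal_levels_give_equal_expected_ratio(self, model):
        t = self._truth(model)
        tab = tq.generate_knockdown_counts(t, depth=200_000, kd_tf_level=2.0,
                                           ctrl_tf_level=2.0, seed=1,
                                           het_variants={"varX"})
        fracs = tab["ref_count"] / (tab["ref_count"] + tab["alt_count"])
        assert abs(fracs.iloc[0] - fracs.iloc[1]) < 0.01

    def test_gene_without_truth_is_balanced(self, model):
        t = self._truth(model)
        tab = tq.generate_knockdown_counts(t, depth=100_000, kd_tf_level=1.0,
                                           ctrl_tf_level=10.0, seed=2,
                                           genes=["geneY"], het_variants=set())
        fracs = tab["ref_count"] / (tab["ref_count"] + tab["alt_count"])
        assert np.allclose(fracs, 0.5, atol=0.01)

    def test_allelic_ratio_follows_occupancy_formula(self, model):
        # occupancy oracle: at T=3 ref/(ref+alt) = 2.84615/9.84615 = 0.28906;
        # at T=300 it is 8.74194/17.71537 = 0.49347; binomial sd at 1e5 ~ 0.0016
        t = self._truth(model)
        tab = tq.generate_knockdown_counts(t, depth=100_000, kd_tf_level=3.0,
                                           ctrl_tf_level=300.0, seed=3,
                                           het_variants={"varX"})
        kd = tab[tab["condition"] == "knockdown"].iloc[0]
        ctrl = tab[tab["condition"] == "control"].iloc[0]
        f_kd = kd["ref_count"] / (kd["ref_count"] + kd["alt_count"])
        f_ctrl = ctrl["ref_count"] / (ctrl["ref_count"] + ctrl["alt_count"])
        ref3, alt3 = 1 + 8 * 3 / 13, 1 + 8 * 3 / 4
        ref300, alt300 = 1 + 8 * 300 / 310, 1 + 8 * 300 / 301
        assert f_kd == pytest.approx(ref3 / (ref3 + alt3), abs=0.007)
        assert f_ctrl == pytest.approx(ref300 / (ref300 + alt300), abs=0.007)

    def test_depth_validation(self, model):
        with pytest.raises(ValueError):
            tq.generate_knockdown_counts(self._truth(model), depth=0,
                                         kd_tf_level=1, ctrl_tf_level=1)


class TestRoundTrip:
    def test_write_load_roundtrip(self, small_study, tmp_path):
        out = write_study(small_study, tmp_path / "study")
        loaded = load_study(out)
        assert loaded.genotypes.individuals == small_study.genotypes.individuals
        assert np.array_equal(loaded.genotypes.dosages, small_study.genotypes.dosages)
        pd.testing.assert_frame_equal(
            loaded.genotypes.variants[["chrom", "pos", "ref", "alt"]],
            small_study.genotypes.variants[["chrom", "pos", "ref", "alt"]],
            check_dtype=False,
        )
        assert loaded.genome == small_study.genome
        assert loaded.annotations.motifs == small_study.annotations.motifs
        assert loaded.annotations.peaks == small_study.annotations.peaks
        assert loaded.regulons == small_study.regulons
        assert loaded.gxe_genes == small_study.gxe_genes
        assert loaded.truth.true_tf_eqtls == small_study.truth.true_tf_eqtls
        t0, l0 = small_study.tissues[0], loaded.tissues[0]
        pd.testing.assert_frame_equal(t0.tpm, l0.tpm)
        pd.testing.assert_frame_equal(t0.covariates, l0.covariates)
        pd.testing.assert_frame_equal(
            small_study.credible_sets, loaded.credible_sets, check_dtype=False
        )
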