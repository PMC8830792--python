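"""Synthetic multi-tissue eQTL cohorts with planted TF-occupancy interactions.

The generator produces everything the discovery pipeline consumes —
genotypes, per-tissue expression, TF levels, functional annotation, credible
sets, allele-specific binding flags, regulons, GxE gene lists, colocalization
tables and knockdown allelic counts — together with a complete ground truth,
so that within-tissue and cross-tissue TF-eQTL discovery can be benchmarked
end to end.

Genotype-by-TF interactions are planted through a saturating TF-occupancy
model: each allele of a regulatory variant binds the TF with its own
dissociation scale, so the allelic fold change of the target gene depends on
the TF level of the sample/tissue (see :class:`tfeqtl.types.OccupancyModel`).
TF levels vary both across tissues (tissue medians spread over the rising
limb of the occupancy curve) and across individuals within a tissue, which
is what powers the two discovery modes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .types import (
    AnnotationSet,
    GenotypeMatrix,
    ModelKind,
    OccupancyModel,
    SimulationTruth,
    SyntheticStudy,
    TissueExpression,
)

_BASES = "ACGT"
_IUPAC_CLASS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# TF-level grid on which the planted allelic-fold-change curve is recorded.
AFC_GRID = tuple(float(t) for t in np.r_[0.0, np.logspace(-2, 3, 21)])


def generate_genotypes(
    n_individuals: int,
    n_variants: int,
    maf_low: float,
    maf_high: float,
    ld_block_size: int = 1,
    seed: int = 0,
    flip_prob: float = 0.03,
    chrom: str = "chr1",
    spacing: int = 1000,
) -> GenotypeMatrix:
    """Hardy-Weinberg dosages in LD blocks.

    Variants are organised in consecutive blocks of ``ld_block_size``.  Each
    block has a single pair of underlying haplotypes per individual drawn at
    a block allele frequency uniform in [maf_low, maf_high]; every variant in
    the block copies those haplotypes with an independent per-allele flip
    probability, so r^2 is high within blocks and ~0 across blocks.
    """
    if n_individuals < 2 or n_variants < 1 or ld_block_size < 1:
        raise ValueError("counts must be positive (n_individuals >= 2)")
    if not (0 < maf_low <= maf_high < 0.5):
        raise ValueError("require 0 < maf_low <= maf_high < 0.5")
    if not (0 <= flip_prob < 0.5):
        raise ValueError("flip_prob must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n_variants / ld_block_size))
    hap = np.empty((2, n_individuals, n_variants), dtype=np.int8)
    for b in range(n_blocks):
        lo, hi = b * ld_block_size, min((b + 1) * ld_block_size, n_variants)
        f = rng.uniform(maf_low, maf_high)
        block_hap = rng.random((2, n_individuals)) < f
        for v in range(lo, hi):
            flips = rng.random((2, n_individuals)) < flip_prob
            hap[:, :, v] = block_hap ^ flips
    dosages = hap.sum(axis=0).astype(float)

    pos = spacing * (1 + np.arange(n_variants))
    ref_idx = rng.integers(0, 4, size=n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_variants)) % 4
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": [_BASES[i] for i in ref_idx],
            "alt": [_BASES[i] for i in alt_idx],
        },
        index=[f"var{i:05d}" for i in range(n_variants)],
    )
    variants["maf"] = np.minimum(dosages.mean(axis=0) / 2, 1 - dosages.mean(axis=0) / 2)
    individuals = [f"ind{i:04d}" for i in range(n_individuals)]
    return GenotypeMatrix(dosages=dosages, individuals=individuals, variants=variants)


def simulate_expression(
    dosage: Sequence[float],
    model: OccupancyModel,
    tf_level: Sequence[float],
    noise_sd: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """Per-sample expression of a gene under the TF-occupancy model.

    Each sample contributes the summed output of its two alleles (``dosage``
    alternate alleles, ``2 - dosage`` reference alleles) at that sample's TF
    level, times multiplicative lognormal noise with log-scale sd
    ``noise_sd``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    d = np.asarray(dosage, dtype=float)
    T = np.asarray(tf_level, dtype=float)
    if np.any(T < 0):
        raise ValueError("tf_level must be non-negative")
    expected = scale * ((2.0 - d) * model.allele_output(T, "ref") + d * model.allele_output(T, "alt"))
    if noise_sd == 0:
        return expected
    if rng is None:
        rng = np.random.default_rng(seed)
    return expected * np.exp(rng.normal(0.0, noise_sd, size=expected.shape))


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a cohort with non-trivial but comfortable discovery
    power: 300 genotyped individuals, 10 tissues of 250 samples each, 100
    candidate genes of which 20% carry a planted TF-eQTL, multiplicative
    expression noise with log-scale sd 0.2, and per-TF tissue medians spread
    log-uniformly over the rising limb of the occupancy curve.
    """

    n_individuals: int = 300
    n_tissues: int = 10
    n_genes: int = 100
    n_tfs: int = 5
    truth_fraction: float = 0.2
    variants_per_gene: int = 3
    maf_low: float = 0.10
    maf_high: float = 0.45
    ld_flip_prob: float = 0.03
    samples_per_tissue: int = 250
    noise_sd: float = 0.2
    tf_spread: float = 0.8          # within-tissue log-scale sd of TF level
    tf_measure_noise: float = 0.1   # measurement noise on TF expression
    tf_median_low: float = 0.02     # lowest per-TF tissue median TF level
    tf_median_high: float = 0.8     # highest; both on the curve's rising limb
    # occupancy model
    basal_rate: float = 1.0
    max_rate: float = 9.0
    K_ref: float = 10.0
    k_alt_low: float = 0.5
    k_alt_high: float = 2.0
    model_kind: ModelKind = ModelKind.affinity_change
    # null-gene structure
    null_eqtl_fraction: float = 0.5   # null genes carrying a TF-independent eQTL
    null_eqtl_sd: float = 0.5         # log2 aFC sd of those constant eQTLs
    confound_fraction: float = 0.1    # null genes driven by a latent cell-type mix
    confound_strength: float = 0.5
    confound_sd: float = 0.5          # log-scale sd of the composition variable
    high_var_tissue: bool = True      # one tissue with exaggerated composition spread
    high_var_sd: float = 1.3
    # covariates
    n_covariates: int = 2
    covariate_strength: float = 0.1
    # annotation
    peak_halfwidth: int = 50
    motif_core_len: int = 8
    decoy_peaks_per_tf: int = 20
    # orthogonal evidence tables
    asb_assay_fraction: float = 0.6
    asb_truth_rate: float = 0.6
    asb_background_rate: float = 0.05
    regulon_truth_rate: float = 0.7
    regulon_background_rate: float = 0.1
    gxe_truth_rate: float = 0.3
    gxe_background_rate: float = 0.05
    coloc_truth_rate: float = 0.5
    coloc_background_rate: float = 0.1
    # knockdown assay
    knockdown_depth: int = 100_000
    kd_tf_level: float = 0.5
    ctrl_tf_level: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.truth_fraction <= 1.0):
            raise ValueError("truth_fraction must be in [0, 1]")
        for name in ("n_individuals", "n_tissues", "n_genes", "n_tfs", "variants_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _make_motif(rng: np.random.Generator, core_len: int) -> str:
    """Random IUPAC consensus: N-flanked core of specific and 2-fold letters."""
    core = [rng.choice(list("ACGT")) for _ in range(core_len)]
    # one or two 2-fold-degenerate letters inside the core
    for i in rng.choice(core_len, size=rng.integers(1, 3), replace=False):
        core[i] = rng.choice(list("RYSWKM"))
    return "N" + "".join(core) + "N"


def _realize(rng: np.random.Generator, consensus: str) -> str:
    return "".join(rng.choice(list(_IUPAC_CLASS[c])) for c in consensus.upper())


def generate_study(config: ScenarioConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a complete synthetic study with ground truth.

    All randomness flows from ``seed`` through a single generator, so a fixed
    (config, seed) pair reproduces the study byte for byte.
    """
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(seed)

    n_variants = cfg.n_genes * cfg.variants_per_gene
    geno = generate_genotypes(
        cfg.n_individuals, n_variants, cfg.maf_low, cfg.maf_high,
        ld_block_size=cfg.variants_per_gene,
        seed=int(rng.integers(2**31)), flip_prob=cfg.ld_flip_prob,
    )
    genes = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    tfs = [f"TF{i:02d}" for i in range(cfg.n_tfs)]
    decoy_tf = tfs[-1]  # reserved as cell-type decoy, never assigned truth
    tissues = [f"tissue{i:02d}" for i in range(cfg.n_tissues)]
    spacing = int(geno.variants["pos"].iloc[1] - geno.variants["pos"].iloc[0]) if n_variants > 1 else 1000
    gene_tss = pd.Series(
        {g: int(geno.variants["pos"].iloc[i * cfg.variants_per_gene] - 100) for i, g in enumerate(genes)}
    )

    # --- ground truth assignment -------------------------------------------------
    n_truth = int(round(cfg.truth_fraction * cfg.n_genes))
    truth_genes = sorted(rng.choice(genes, size=n_truth, replace=False))
    assignable = tfs[:-1] if cfg.n_tfs > 1 else tfs
    truth_tf = {g: str(rng.choice(assignable)) for g in truth_genes}
    causal_variant = {
        g: geno.variant_ids[genes.index(g) * cfg.variants_per_gene] for g in truth_genes
    }
    models: Dict[Tuple[str, str, str], OccupancyModel] = {}
    for g in truth_genes:
        k_alt = float(np.exp(rng.uniform(np.log(cfg.k_alt_low), np.log(cfg.k_alt_high))))
        key = (truth_tf[g], g, causal_variant[g])
        models[key] = OccupancyModel(
            basal_rate=cfg.basal_rate, max_rate=cfg.max_rate,
            K_ref=cfg.K_ref, K_alt=k_alt, model_kind=cfg.model_kind,
        )
    planted_curves = {
        key: {t: float(m.log2_afc(t)) if t > 0 else 0.0 for t in AFC_GRID}
        for key, m in models.items()
    }

    # --- TF levels ---------------------------------------------------------------
    # Per TF, tissue medians log-spaced over the rising limb, shuffled across
    # tissues so different tissues are informative for different TFs.
    tf_medians = pd.DataFrame(index=tfs, columns=tissues, dtype=float)
    base = np.exp(np.linspace(np.log(cfg.tf_median_low), np.log(cfg.tf_median_high), cfg.n_tissues))
    for tf in tfs:
        tf_medians.loc[tf] = rng.permutation(base)

    # --- null-gene structure -----------------------------------------------------
    null_genes = [g for g in genes if g not in truth_tf]
    null_afc = {g: 0.0 for g in null_genes}
    n_eqtl = int(round(cfg.null_eqtl_fraction * len(null_genes)))
    for g in rng.choice(null_genes, size=n_eqtl, replace=False):
        null_afc[str(g)] = float(rng.normal(0.0, cfg.null_eqtl_sd))
    n_conf = int(round(cfg.confound_fraction * len(null_genes)))
    confounded = set(map(str, rng.choice(null_genes, size=n_conf, replace=False))) if n_conf else set()
    baseline = np.exp(rng.normal(np.log(50.0), 1.0, size=cfg.n_genes))
    baseline = pd.Series(baseline, index=genes)

    # --- per-tissue expression ---------------------------------------------------
    tissue_objs: List[TissueExpression] = []
    xcell: Dict[str, pd.DataFrame] = {}
    conf_summary: Dict[str, Tuple[float, float]] = {}
    high_var_tissue = tissues[0] if cfg.high_var_tissue else None
    n_samp = min(cfg.samples_per_tissue, cfg.n_individuals)
    ind_index = pd.Index(geno.individuals)
    for tis in tissues:
        samp_idx = np.sort(rng.choice(cfg.n_individuals, size=n_samp, replace=False))
        samples = list(ind_index[samp_idx])
        # latent cell-type composition and TF levels for this tissue
        c_sd = cfg.high_var_sd if tis == high_var_tissue else cfg.confound_sd
        comp = np.exp(rng.normal(0.0, c_sd, size=n_samp))
        conf_summary[tis] = (float(comp.mean()), float(comp.var()))
        T = {
            tf: tf_medians.loc[tf, tis] * np.exp(rng.normal(0.0, cfg.tf_spread, size=n_samp))
            for tf in tfs
        }
        covs = rng.normal(size=(n_samp, cfg.n_covariates))
        cov_effect = np.exp(cfg.covariate_strength * covs[:, 0]) if cfg.n_covariates else 1.0

        expr = np.empty((cfg.n_genes + cfg.n_tfs, n_samp))
        for i, g in enumerate(genes):
            if g in truth_tf:
                key = (truth_tf[g], g, causal_variant[g])
                d = geno.dosages[samp_idx, geno.variants.index.get_loc(causal_variant[g])]
                e = simulate_expression(
                    d, models[key], T[truth_tf[g]], cfg.noise_sd, rng=rng,
                    scale=baseline[g] / 2.0,
                )
            else:
                d = geno.dosages[samp_idx, geno.variants.index.get_loc(
                    geno.variant_ids[i * cfg.variants_per_gene])]
                fold = 2.0 ** null_afc[g]
                e = baseline[g] * ((2.0 - d) + d * fold) / 2.0
                e = e * np.exp(rng.normal(0.0, cfg.noise_sd, size=n_samp))
                if g in confounded:
                    e = e * comp ** cfg.confound_strength
            expr[i] = e * cov_effect
        for j, tf in enumerate(tfs):
            e = T[tf] * np.exp(rng.normal(0.0, cfg.tf_measure_noise, size=n_samp))
            if tf == decoy_tf and cfg.confound_fraction > 0:
                e = e * comp ** cfg.confound_strength
            expr[cfg.n_genes + j] = e * cov_effect

        tpm = pd.DataFrame(expr, index=genes + tfs, columns=samples)
        covariates = pd.DataFrame(
            covs, index=samples, columns=[f"cov{k+1}" for k in range(cfg.n_covariates)]
        )
        tissue_objs.append(TissueExpression(tissue=tis, tpm=tpm, covariates=covariates))
        # XCell-style scores: two complementary cell types driven by the latent
        # composition, plus a noisy dendritic-cell estimate meant to be dropped.
        s1 = comp / (1.0 + comp)
        xcell[tis] = pd.DataFrame(
            {
                "celltypeA": s1,
                "celltypeB": np.clip(1.0 - s1 + rng.normal(0, 0.02, n_samp), 0, 1),
                "aDC": rng.uniform(0, 1, size=n_samp),
            },
            index=samples,
        )

    # --- protein medians (TFs x tissues) ----------------------------------------
    protein = tf_medians * np.exp(rng.normal(0.0, 0.3, size=tf_medians.shape))
    protein_medians = protein.round(3)

    # --- genome + annotations ----------------------------------------------------
    motifs = {tf: _make_motif(rng, cfg.motif_core_len) for tf in tfs}
    glen = int(geno.variants["pos"].max() + spacing)
    genome_arr = rng.choice(list(_BASES), size=glen)
    # assign an annotation TF per variant: truth TF for causal variants,
    # random TF otherwise, so every credible variant can pass the filters
    assigned_tf = {}
    for vid in geno.variant_ids:
        assigned_tf[vid] = str(rng.choice(tfs))
    for g in truth_genes:
        assigned_tf[causal_variant[g]] = truth_tf[g]
    peaks: Dict[str, List[Tuple[str, int, int]]] = {tf: [] for tf in tfs}
    for vid, row in geno.variants.iterrows():
        tf = assigned_tf[vid]
        pos = int(row["pos"])
        consensus = motifs[tf]
        word = _realize(rng, consensus)
        L = len(word)
        # keep the variant inside the trimmed (non-N) core of the motif so the
        # reference allele is guaranteed to match after end-trimming
        off = int(rng.integers(1, L - 1))
        start = pos - 1 - off
        genome_arr[start:start + L] = list(word)
        peaks[tf].append(("chr1", pos - 1 - cfg.peak_halfwidth, pos + cfg.peak_halfwidth))
    # refs/alts consistent with the planted genome
    refs, alts = [], []
    for vid, row in geno.variants.iterrows():
        pos = int(row["pos"])
        ref = genome_arr[pos - 1]
        off_class = _IUPAC_CLASS[motifs[assigned_tf[vid]][0]]
        others = [b for b in _BASES if b != ref]
        # prefer an alternate allele outside the motif class at this position
        breaking = [b for b in others if b not in off_class] or others
        alts.append(str(rng.choice(breaking if vid in causal_variant.values() else others)))
        refs.append(str(ref))
    geno.variants["ref"] = refs
    geno.variants["alt"] = alts
    for tf in tfs:
        for _ in range(cfg.decoy_peaks_per_tf):
            s = int(rng.integers(0, glen - 400))
            peaks[tf].append(("chr1", s, s + int(rng.integers(100, 400))))
    annotations = AnnotationSet(peaks=peaks, motifs=motifs)
    genome = {"chr1": "".join(genome_arr)}

    # --- credible sets -----------------------------------------------------------
    rows = []
    for i, g in enumerate(genes):
        for v in range(cfg.variants_per_gene):
            vid = geno.variant_ids[i * cfg.variants_per_gene + v]
            n_src = min(int(rng.integers(1, 4)), len(tissues))
            for tis in rng.choice(tissues, size=n_src, replace=False):
                rows.append((vid, g, str(tis)))
    credible_sets = pd.DataFrame(rows, columns=["variant", "gene", "tissue"])

    # --- ASB table ---------------------------------------------------------------
    truth_keys = {(truth_tf[g], causal_variant[g]) for g in truth_genes}
    assayed = set(
        map(str, rng.choice(geno.variant_ids,
                            size=int(cfg.asb_assay_fraction * n_variants), replace=False))
    ) | {v for _, v in truth_keys}
    asb_rows = []
    for vid in sorted(assayed):
        for tf in tfs:
            rate = cfg.asb_truth_rate if (tf, vid) in truth_keys else cfg.asb_background_rate
            asb_rows.append((vid, tf, bool(rng.random() < rate)))
    asb_table = pd.DataFrame(asb_rows, columns=["variant", "tf", "asb"])

    # --- regulons, GxE genes, colocalization -------------------------------------
    regulons: Dict[str, Dict[str, Set[str]]] = {}
    for rtype in ("curated", "chipseq", "motif", "coexpression"):
        regulons[rtype] = {}
        for tf in tfs:
            members = {
                g for g in truth_genes
                if truth_tf[g] == tf and rng.random() < cfg.regulon_truth_rate
            }
            members |= {str(g) for g in genes if rng.random() < cfg.regulon_background_rate}
            regulons[rtype][tf] = members
    regulons["any"] = {
        tf: set().union(*(regulons[rt][tf] for rt in ("curated", "chipseq", "motif", "coexpression")))
        for tf in tfs
    }
    gxe_genes = {
        g for g in genes
        if rng.random() < (cfg.gxe_truth_rate if g in truth_tf else cfg.gxe_background_rate)
    }
    traits = ["traitA", "traitB", "traitC"]
    coloc_rows = []
    for i, g in enumerate(genes):
        rate = cfg.coloc_truth_rate if g in truth_tf else cfg.coloc_background_rate
        if rng.random() < rate:
            lead = causal_variant.get(g, geno.variant_ids[i * cfg.variants_per_gene])
            coloc_rows.append(
                (g, str(rng.choice(tissues)), str(rng.choice(traits)),
                 float(np.round(rng.uniform(0.2, 1.0), 3)), lead)
            )
    coloc_table = pd.DataFrame(coloc_rows, columns=["gene", "tissue", "trait", "rcp", "lead_variant"])

    truth = SimulationTruth(
        true_tf_eqtls={(truth_tf[g], g, causal_variant[g]) for g in truth_genes},
        planted_afc_curve=planted_curves,
        confounds=[("latent-composition", {t: conf_summary[t] for t in tissues})],
        seed=seed,
        models=models,
    )

    # --- knockdown allelic counts (cell line = first genotyped individual) -------
    kd_tf = tfs[0]
    het_variants = {
        vid for vid in geno.variant_ids if geno.dosages[0, geno.variants.index.get_loc(vid)] == 1
    }
    allelic_counts = generate_knockdown_counts(
        truth, depth=cfg.knockdown_depth, kd_tf_level=cfg.kd_tf_level,
        ctrl_tf_level=cfg.ctrl_tf_level, seed=int(rng.integers(2**31)),
        tf=kd_tf, genes=genes, het_variants=het_variants,
    )

    return SyntheticStudy(
        genotypes=geno,
        tissues=tissue_objs,
        tf_ids=tfs,
        protein_medians=protein_medians,
        annotations=annotations,
        credible_sets=credible_sets,
        asb_table=asb_table,
        regulons=regulons,
        gxe_genes=gxe_genes,
        coloc_table=coloc_table,
        allelic_counts=allelic_counts,
        genome=genome,
        truth=truth,
        gene_tss=gene_tss,
        xcell_scores=xcell,
    )


def generate_knockdown_counts(
    truth: SimulationTruth,
    depth: int,
    kd_tf_level: float,
    ctrl_tf_level: float,
    seed: int = 0,
    tf: str | None = None,
    genes: Iterable[str] | None = None,
    het_variants: Set[str] | None = None,
) -> pd.DataFrame:
    """Allele-specific read counts of a TF-knockdown vs control experiment.

    Genes regulated by ``tf`` through a heterozygous regulatory variant get
    per-condition allelic ratios from the occupancy model evaluated at that
    condition's TF level; all other genes are balanced (ref fraction 0.5).
    Counts are binomial at ``depth`` reads per condition; a small fraction of
    "other" (mismapped) reads is not modelled.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    het_variants = het_variants if het_variants is not None else set()
    by_gene = {}
    for (f, g, v), model in truth.models.items():
        if tf is None or f == tf:
            by_gene[g] = (v, model)
    if genes is None:
        genes = sorted(by_gene)
    rows = []
    for g in genes:
        for cond, level in (("knockdown", kd_tf_level), ("control", ctrl_tf_level)):
            if g in by_gene and by_gene[g][0] in het_variants:
                _, model = by_gene[g]
                ref_out = float(model.allele_output(level, "ref"))
                alt_out = float(model.allele_output(level, "alt"))
                p_ref = ref_out / (ref_out + alt_out)
            else:
                p_ref = 0.5
            ref = int(rng.binomial(depth, p_ref))
            rows.append((g, f"cs_{g}", cond, ref, depth - ref, 0))
    return pd.DataFrame(
        rows, columns=["gene", "variant", "condition", "ref_count", "alt_count", "other_count"]
    )
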