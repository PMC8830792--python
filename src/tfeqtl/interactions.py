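"""Within-tissue genotype x TF-level interaction discovery.

For each analysed tissue and TF, normalized target-gene expression is
regressed on genotype dosage, normalized TF expression, their product and
tissue covariates; the two-sided t-test on the interaction coefficient is
the evidence for a TF-eQTL.  Per gene the top variant's p-value is corrected
by the effective number of independent variants (eigenvalue-based), then
Benjamini-Hochberg adjusted across genes within the (tissue, TF) analysis.

Tissue selection (expression clustering, one representative per cluster) and
exclusion of tissues with highly variable cell-type composition live here
too, as they gate which tissues are analysed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .types import GenotypeMatrix, SyntheticStudy, TissueExpression

logger = logging.getLogger(__name__)


class Untestable(ValueError):
    """A gene/variant cannot be tested (constant data or rank deficiency)."""


def inverse_normal_transform(values: Sequence[float]) -> np.ndarray:
    """Rank-based inverse normal transform: Phi^-1((rank - 0.5) / n).

    Ties get average ranks.  A constant vector is untestable.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector with >= 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if np.all(x == x[0]):
        raise Untestable("constant vector has no rank information")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / x.size)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def select_tissues(
    median_tpm: pd.DataFrame,
    sample_sizes: Mapping[str, int],
    k: int,
    excluded: Set[str] = frozenset(),
) -> List[str]:
    """Representative tissues: Ward clustering of median-TPM profiles.

    Tissues (rows of ``median_tpm``) are clustered by Euclidean distance of
    their median-TPM vectors with the Ward minimum-variance update; the tree
    is cut into ``k`` clusters and the non-excluded tissue with the largest
    sample size is taken from each cluster (clusters whose tissues are all
    excluded contribute nothing).
    """
    tissues = list(median_tpm.index)
    if k > len(tissues):
        raise ValueError("k exceeds the number of tissues")
    if k == len(tissues):
        labels = np.arange(1, k + 1)
    else:
        Z = linkage(median_tpm.to_numpy(dtype=float), method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust")
    chosen: List[str] = []
    for c in range(1, k + 1):
        members = [t for t, lab in zip(tissues, labels) if lab == c and t not in excluded]
        if not members:
            continue
        chosen.append(max(members, key=lambda t: (sample_sizes[t], t)))
    return sorted(chosen)


def flag_celltype_variance(
    xcell_scores: Mapping[str, pd.DataFrame],
    drop_celltypes: Set[str] = frozenset({"aDC", "iDC"}),
    threshold: float = 0.04,
) -> Set[str]:
    """Tissues whose cell-type composition varies too much across samples.

    Per tissue, the maximum across retained cell types of the across-sample
    score variance (population variance; scores live in [0, 1]) is compared
    to ``threshold``; strictly larger flags the tissue.  Cell types in
    ``drop_celltypes`` (unstable estimates) are ignored.
    """
    flagged = set()
    for tissue, scores in xcell_scores.items():
        keep = [c for c in scores.columns if c not in drop_celltypes]
        if not keep:
            continue
        var = scores[keep].to_numpy(dtype=float).var(axis=0, ddof=0)
        if var.size and var.max() > threshold:
            flagged.add(tissue)
    return flagged


@dataclass(frozen=True)
class InteractionFit:
    """One genotype x TF interaction regression."""

    beta_g: float
    beta_t: float
    beta_gxt: float
    se_gxt: float
    p_nominal: float
    n_samples: int


def _ols(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, int]:
    """OLS coefficients, standard errors and residual dof; Untestable if singular."""
    n, p = X.shape
    if n <= p:
        raise Untestable(f"n = {n} <= p = {p}")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise Untestable("design matrix is rank deficient")
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0, None))
    return beta, se, dof


def fit_interaction(
    expr: Sequence[float],
    dosage: Sequence[float],
    tf: Sequence[float],
    covariates: np.ndarray | None = None,
) -> InteractionFit:
    """OLS of expression on [1, dosage, tf, dosage*tf, covariates].

    Inputs are used as given (normalize upstream); the reported p-value is
    the two-sided t-test on the interaction coefficient.
    """
    y = np.asarray(expr, dtype=float)
    g = np.asarray(dosage, dtype=float)
    t = np.asarray(tf, dtype=float)
    n = y.size
    if g.size != n or t.size != n:
        raise ValueError("expr, dosage and tf must be aligned")
    cols = [np.ones(n), g, t, g * t]
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float)
        C = C.reshape(n, -1)
        cols.extend(C.T)
    X = np.column_stack(cols)
    beta, se, dof = _ols(X, y)
    tstat = beta[3] / se[3] if se[3] > 0 else np.inf * np.sign(beta[3])
    p = float(2.0 * stats.t.sf(abs(tstat), dof))
    return InteractionFit(
        beta_g=float(beta[1]), beta_t=float(beta[2]), beta_gxt=float(beta[3]),
        se_gxt=float(se[3]), p_nominal=max(p, np.finfo(float).tiny), n_samples=n,
    )


def meff(dosage_matrix: np.ndarray, variance_fraction: float = 0.95) -> int:
    """Effective number of independent variants among correlated dosages.

    The smallest number of leading eigenvalues of the variant correlation
    matrix whose sum reaches ``variance_fraction`` of the total.  Constant
    and exactly duplicated variant columns carry no extra test and are
    dropped first; if nothing informative remains, meff is 1.
    """
    X = np.asarray(dosage_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need a samples x variants matrix")
    keep = X.std(axis=0) > 0
    if not np.any(keep):
        logger.warning("all variants constant; meff = 1")
        return 1
    X = X[:, keep]
    seen: set = set()
    cols = []
    for j in range(X.shape[1]):
        key = X[:, j].tobytes()
        if key not in seen:
            seen.add(key)
            cols.append(j)
    X = X[:, cols]
    m = X.shape[1]
    if m == 1:
        return 1
    corr = np.corrcoef(X, rowvar=False)
    ev = np.clip(np.linalg.eigvalsh(corr)[::-1], 0.0, None)
    frac = np.cumsum(ev) / ev.sum()
    return int(np.searchsorted(frac, variance_fraction - 1e-12) + 1)


def normalized_expression(
    tissue: TissueExpression, genes: Iterable[str]
) -> Dict[str, np.ndarray]:
    """Inverse-normal-transformed expression per gene; untestable genes omitted."""
    out: Dict[str, np.ndarray] = {}
    for g in genes:
        if g not in tissue.tpm.index:
            continue
        try:
            out[g] = inverse_normal_transform(tissue.tpm.loc[g].to_numpy())
        except Untestable:
            continue
    return out


def call_eqtls(
    study: SyntheticStudy,
    tissue: TissueExpression,
    candidates: pd.DataFrame,
    fdr: float = 0.05,
    norm_expr: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Nominal dosage-regression eQTL caller with BH control per tissue.

    For every candidate eVariant-eGene pair, normalized expression is
    regressed on dosage (plus tissue covariates) and the dosage p-values are
    BH-adjusted across pairs within the tissue.  Serves as the eQTL
    significance table for synthetic studies.
    """
    samples = tissue.samples
    covs = tissue.covariates.to_numpy(dtype=float) if len(tissue.covariates.columns) else None
    if norm_expr is None:
        norm_expr = normalized_expression(tissue, set(candidates["gene"]))
    rows = []
    for _, row in candidates.iterrows():
        gene, vid = row["gene"], row["variant"]
        y = norm_expr.get(gene)
        if y is None:
            continue
        g = study.genotypes.dosage(vid, samples)
        cols = [np.ones(len(y)), g]
        if covs is not None:
            cols.extend(covs.T)
        X = np.column_stack(cols)
        try:
            beta, se, dof = _ols(X, y)
        except Untestable:
            continue
        tstat = beta[1] / se[1] if se[1] > 0 else 0.0
        p = float(2.0 * stats.t.sf(abs(tstat), dof))
        rows.append((vid, gene, tissue.tissue, float(beta[1]), p))
    out = pd.DataFrame(rows, columns=["variant", "gene", "tissue", "beta", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] <= fdr
    else:
        out["q"] = []
        out["significant"] = []
    return out


def within_tissue_discovery(
    candidates: pd.DataFrame,
    study: SyntheticStudy,
    tissue: str | TissueExpression,
    tf: str,
    fdr: float = 0.05,
    eqtl_table: pd.DataFrame | None = None,
    cis_window: float = 1e6,
    variance_fraction: float = 0.95,
    norm_expr: Mapping[str, np.ndarray] | None = None,
    meff_cache: Dict[Tuple[str, Tuple[str, ...]], int] | None = None,
) -> pd.DataFrame:
    """Gene-level TF-eQTL results for one (tissue, TF) analysis.

    Per gene, every candidate variant within ``cis_window`` of the TSS is
    fitted with :func:`fit_interaction`; the minimum nominal p is multiplied
    by the gene's effective test count (capped at 1) and BH-adjusted across
    genes.  A gene passes if q <= fdr, its top variant is a significant eQTL
    in this tissue (per ``eqtl_table``), and the gene is not the TF itself.
    """
    tis = study.tissue(tissue) if isinstance(tissue, str) else tissue
    samples = tis.samples
    if tf not in tis.tpm.index:
        raise KeyError(f"TF {tf} absent from expression of {tis.tissue}")
    tf_norm = inverse_normal_transform(tis.tpm.loc[tf].to_numpy())
    covs = tis.covariates.to_numpy(dtype=float) if len(tis.covariates.columns) else None
    if eqtl_table is None:
        eqtl_table = call_eqtls(study, tis, candidates, fdr=fdr)
    sig_eqtl = set(
        zip(eqtl_table.loc[eqtl_table["significant"], "variant"],
            eqtl_table.loc[eqtl_table["significant"], "gene"])
    )
    ind_idx = pd.Index(study.genotypes.individuals).get_indexer(samples)
    if norm_expr is None:
        norm_expr = normalized_expression(tis, set(candidates["gene"]))
    if meff_cache is None:
        meff_cache = {}

    results = []
    n_skipped = 0
    for gene, grp in candidates.groupby("gene", sort=True):
        if gene not in norm_expr and gene not in tis.tpm.index:
            n_skipped += 1
            continue
        tss = study.gene_tss.get(gene)
        vids = []
        for vid in grp["variant"]:
            pos = study.genotypes.variants.loc[vid, "pos"]
            if tss is None or abs(int(pos) - int(tss)) <= cis_window:
                vids.append(vid)
        if not vids:
            n_skipped += 1
            continue
        y = norm_expr.get(gene)
        if y is None:
            n_skipped += 1
            continue
        fits: Dict[str, InteractionFit] = {}
        dosages = {}
        for vid in vids:
            d = study.genotypes.dosages[ind_idx, study.genotypes.variants.index.get_loc(vid)]
            try:
                fits[vid] = fit_interaction(y, d, tf_norm, covs)
                dosages[vid] = d
            except Untestable:
                continue
        if not fits:
            n_skipped += 1
            continue
        top = min(fits, key=lambda v: fits[v].p_nominal)
        cache_key = (tis.tissue, tuple(fits))
        m = meff_cache.get(cache_key)
        if m is None:
            D = np.column_stack([dosages[v] for v in fits])
            m = meff(D, variance_fraction)
            meff_cache[cache_key] = m
        p_m = min(1.0, m * fits[top].p_nominal)
        results.append(
            {
                "gene": gene, "variant": top, "tf": tf, "tissue": tis.tissue,
                "beta_gxt": fits[top].beta_gxt, "p_nominal": fits[top].p_nominal,
                "meff": m, "p_meff": p_m, "n_variants": len(fits),
            }
        )
    if n_skipped:
        logger.info("%s/%s: %d genes without testable variants omitted", tis.tissue, tf, n_skipped)
    out = pd.DataFrame(
        results,
        columns=["gene", "variant", "tf", "tissue", "beta_gxt", "p_nominal", "meff", "p_meff", "n_variants"],
    )
    if len(out):
        out["q_bh"] = bh_adjust(out["p_meff"].to_numpy())
        out["eqtl_sig"] = [
            (v, g) in sig_eqtl for v, g in zip(out["variant"], out["gene"])
        ]
        out["pass"] = (out["q_bh"] <= fdr) & out["eqtl_sig"] & (out["gene"] != tf)
    else:
        out["q_bh"] = []
        out["eqtl_sig"] = []
        out["pass"] = []
    return out
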