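"""Cross-tissue correlation of eQTL effect sizes with TF levels.

The eQTL effect size in each tissue is the log2 allelic fold change (aFC):
the log2 ratio of expression driven by the alternate vs the reference
allele, estimated by log-linear regression of expression on dosage.  For
each (TF, gene) pair, the aFC of every candidate variant across tissues is
Spearman-correlated with the TF's per-tissue level — median TPM in
expression mode, median protein abundance in protein mode — over tissues
where the target gene is expressed.  Gene-level p-values are corrected by
the effective number of independent variants (shared with the within-tissue
stage) and BH-adjusted across genes per TF.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import chain, permutations
from math import factorial
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .interactions import bh_adjust, meff
from .types import GenotypeMatrix, SyntheticStudy

logger = logging.getLogger(__name__)

DEFAULT_AFC_CAP = float(np.log2(100.0))


@dataclass(frozen=True)
class AFCEstimate:
    """log2 allelic fold change of one eQTL in one tissue."""

    afc: float
    capped: bool


def estimate_afc(
    expr_tpm: Sequence[float],
    dosage: Sequence[float],
    covariates: np.ndarray | None = None,
    cap: float = DEFAULT_AFC_CAP,
    pseudocount: float = 1.0,
) -> AFCEstimate:
    """aFC by log-linear regression of expression on dosage.

    log2(TPM + pseudocount) is residualized on covariates (if any) and
    regressed on dosage; since dosage spans two allele copies, aFC is twice
    the per-dosage slope.  Positive aFC means the alternate allele drives
    higher expression.  Estimates are clipped to +/- ``cap`` (default
    log2 100, the conventional bound for fold-change estimates) with the
    ``capped`` flag set.  A single observed genotype group is inestimable
    and yields NaN.
    """
    y = np.log2(np.asarray(expr_tpm, dtype=float) + pseudocount)
    g = np.asarray(dosage, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g)
    y, g = y[ok], g[ok]
    if np.unique(g).size < 2:
        return AFCEstimate(afc=np.nan, capped=False)
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float).reshape(ok.size, -1)[ok]
        Xc = np.column_stack([np.ones(len(y)), C])
        y = y - Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
    X = np.column_stack([np.ones(len(y)), g])
    slope = float(np.linalg.lstsq(X, y, rcond=None)[0][1])
    afc = 2.0 * slope
    if abs(afc) > cap:
        return AFCEstimate(afc=float(np.sign(afc) * cap), capped=True)
    return AFCEstimate(afc=afc, capped=False)


@lru_cache(maxsize=None)
def _exact_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (tie-free null), n <= 10."""
    if n > 10:
        raise ValueError("exact null only tabulated for n <= 10")
    nfact = factorial(n)
    perms = np.fromiter(
        chain.from_iterable(permutations(range(n))), dtype=np.int8, count=n * nfact
    ).reshape(nfact, n)
    idx = np.arange(n)
    D = ((perms - idx) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * D / (n * (n * n - 1.0))
    return np.sort(np.abs(rho))


def _exact_spearman_p(rho: float, n: int) -> float:
    null = _exact_null_abs_rho(n)
    k = null.size - np.searchsorted(null, abs(rho) - 1e-12, side="left")
    return float(k) / null.size


@dataclass(frozen=True)
class CorrResult:
    """One cross-tissue Spearman correlation."""

    rho: float
    p: float
    n: int
    reason: str = ""


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rho and two-sided p.

    rho is Pearson correlation of average ranks.  The p-value uses the exact
    tie-free permutation null for n <= 10 (t approximation as fallback when
    ties are present) and the t approximation for larger n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.std(rx) == 0 or np.std(ry) == 0:
        return np.nan, np.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    has_ties = np.unique(rx).size < n or np.unique(ry).size < n
    if n <= 10 and not has_ties:
        return rho, _exact_spearman_p(rho, n)
    if abs(rho) >= 1.0:
        return rho, 0.0
    tstat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return rho, float(2.0 * stats.t.sf(abs(tstat), n - 2))


def cross_tissue_correlation(
    afc_by_tissue: Sequence[float],
    tf_by_tissue: Sequence[float],
    expressed_mask: Sequence[bool] | None = None,
    min_points: int = 5,
) -> CorrResult:
    """Spearman correlation of per-tissue aFC with per-tissue TF level.

    Pairs are restricted to tissues where the target gene is expressed
    (``expressed_mask``) and both values are non-missing (pairwise
    deletion).  Too few points, or zero rank variance, yields a missing
    result with a reason code.
    """
    a = np.asarray(afc_by_tissue, dtype=float)
    t = np.asarray(tf_by_tissue, dtype=float)
    if a.size != t.size:
        raise ValueError("vectors must be tissue-aligned")
    keep = np.isfinite(a) & np.isfinite(t)
    if expressed_mask is not None:
        keep &= np.asarray(expressed_mask, dtype=bool)
    n = int(keep.sum())
    if n < min_points:
        return CorrResult(np.nan, np.nan, n, reason="too_few_tissues")
    rho, p = spearman(a[keep], t[keep])
    if not np.isfinite(rho):
        return CorrResult(np.nan, np.nan, n, reason="zero_rank_variance")
    return CorrResult(rho, p, n)


def tf_levels_by_tissue(study: SyntheticStudy, mode: str = "expression") -> pd.DataFrame:
    """Per-TF per-tissue level: median TPM (expression) or protein medians."""
    if mode == "protein":
        return study.protein_medians.copy()
    if mode != "expression":
        raise ValueError("mode must be 'expression' or 'protein'")
    cols = {}
    for tis in study.tissues:
        cols[tis.tissue] = tis.tpm.loc[study.tf_ids].median(axis=1)
    return pd.DataFrame(cols)


def afc_table(
    study: SyntheticStudy,
    candidates: pd.DataFrame,
    cap: float = DEFAULT_AFC_CAP,
    pseudocount: float = 1.0,
    use_covariates: bool = True,
) -> pd.DataFrame:
    """aFC of every candidate eVariant-eGene pair in every tissue.

    Indexed by (variant, gene) with one column per tissue; inestimable
    entries are NaN.
    """
    pairs = list(candidates[["variant", "gene"]].itertuples(index=False, name=None))
    data = np.full((len(pairs), len(study.tissues)), np.nan)
    ind_index = pd.Index(study.genotypes.individuals)
    var_index = study.genotypes.variants.index
    for j, tis in enumerate(study.tissues):
        samp_idx = ind_index.get_indexer(tis.samples)
        covs = tis.covariates.to_numpy(dtype=float) if use_covariates and len(tis.covariates.columns) else None
        for i, (vid, gene) in enumerate(pairs):
            if gene not in tis.tpm.index:
                continue
            est = estimate_afc(
                tis.tpm.loc[gene].to_numpy(),
                study.genotypes.dosages[samp_idx, var_index.get_loc(vid)],
                covariates=covs, cap=cap, pseudocount=pseudocount,
            )
            data[i, j] = est.afc
    return pd.DataFrame(
        data, index=pd.MultiIndex.from_tuples(pairs, names=["variant", "gene"]),
        columns=[t.tissue for t in study.tissues],
    )


def expressed_mask(study: SyntheticStudy, genes: Sequence[str]) -> pd.DataFrame:
    """Genes x tissues flag: median TPM of the gene > 0 in that tissue."""
    cols = {}
    for tis in study.tissues:
        med = tis.tpm.median(axis=1)
        cols[tis.tissue] = med.reindex(genes).fillna(0.0) > 0
    return pd.DataFrame(cols, index=genes)


def cross_tissue_discovery(
    candidates: pd.DataFrame,
    afc_tab: pd.DataFrame,
    tf_levels: pd.DataFrame,
    geno: GenotypeMatrix,
    mode: str = "expression",
    fdr: float = 0.05,
    min_points: int = 5,
    min_unique_protein: int = 20,
    gene_expressed: pd.DataFrame | None = None,
    variance_fraction: float = 0.95,
) -> pd.DataFrame:
    """Cross-tissue TF-eQTL discovery over all (TF, gene) pairs.

    Every candidate variant of a gene is correlated with each TF's level
    profile; the gene's top variant (minimum nominal p) is corrected by the
    gene's effective variant count and BH-adjusted across genes per TF.
    In protein mode, TFs with fewer than ``min_unique_protein`` distinct
    level values are reported untested.
    """
    tissues = list(afc_tab.columns)
    tf_levels = tf_levels.reindex(columns=tissues)
    by_gene = {g: list(grp["variant"]) for g, grp in candidates.groupby("gene", sort=True)}
    gene_meff = {}
    for g, vids in by_gene.items():
        D = np.column_stack([geno.dosage(v) for v in vids])
        gene_meff[g] = meff(D, variance_fraction)
    rows = []
    for tf in tf_levels.index:
        levels = tf_levels.loc[tf].to_numpy(dtype=float)
        tested = True
        if mode == "protein":
            n_unique = np.unique(levels[np.isfinite(levels)]).size
            tested = n_unique >= min_unique_protein
        for g, vids in by_gene.items():
            if g == tf:
                continue
            if not tested:
                rows.append(
                    {"tf": tf, "gene": g, "variant": None, "mode": mode, "rho": np.nan,
                     "n_tissues": 0, "p_nominal": np.nan, "meff": gene_meff[g],
                     "p_meff": np.nan, "tested": False}
                )
                continue
            mask = (
                gene_expressed.loc[g, tissues].to_numpy(dtype=bool)
                if gene_expressed is not None else None
            )
            best = None
            for vid in vids:
                res = cross_tissue_correlation(
                    afc_tab.loc[(vid, g)].to_numpy(dtype=float), levels,
                    expressed_mask=mask, min_points=min_points,
                )
                if np.isfinite(res.p) and (best is None or res.p < best[1].p):
                    best = (vid, res)
            if best is None:
                continue
            vid, res = best
            rows.append(
                {"tf": tf, "gene": g, "variant": vid, "mode": mode, "rho": res.rho,
                 "n_tissues": res.n, "p_nominal": res.p, "meff": gene_meff[g],
                 "p_meff": min(1.0, gene_meff[g] * res.p), "tested": True}
            )
    out = pd.DataFrame(
        rows, columns=["tf", "gene", "variant", "mode", "rho", "n_tissues",
                       "p_nominal", "meff", "p_meff", "tested"],
    )
    out["q_bh"] = np.nan
    out["pass"] = False
    for tf in out["tf"].unique():
        sel = (out["tf"] == tf) & out["tested"]
        if sel.any():
            q = bh_adjust(out.loc[sel, "p_meff"].to_numpy())
            out.loc[sel, "q_bh"] = q
            out.loc[sel, "pass"] = q <= fdr
    return out
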