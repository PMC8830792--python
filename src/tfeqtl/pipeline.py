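"""End-to-end TF-eQTL discovery over a study.

Wires the stages together in the order the analysis runs: candidate-variant
filtering, tissue exclusion by cell-type-composition variance, per-tissue
eQTL calling, within-tissue interaction discovery for every (tissue, TF)
analysis, cross-tissue aFC/TF-level correlation, dual-evidence ledger
construction, and the orthogonal enrichment statistics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Set, Tuple

import pandas as pd

from .cross_tissue import afc_table, cross_tissue_discovery, expressed_mask, tf_levels_by_tissue
from .enrichment import EnrichmentResult, asb_enrichment, overlap_enrichment
from .filtering import build_candidates
from .integration import build_dual_evidence
from .interactions import (
    call_eqtls,
    flag_celltype_variance,
    select_tissues,
    within_tissue_discovery,
)
from .types import SyntheticStudy

logger = logging.getLogger(__name__)


def annotated_variants(candidates: pd.DataFrame, kind: str = "peak") -> Dict[str, Set[str]]:
    """Per-TF sets of candidate variants carrying a peak / motif annotation."""
    col = {"peak": "peak_tfs", "motif": "motif_tfs"}[kind]
    out: Dict[str, Set[str]] = {}
    for vid, tfs in zip(candidates["variant"], candidates[col]):
        for tf in str(tfs).split(","):
            if tf:
                out.setdefault(tf, set()).add(vid)
    return out


@dataclass
class DiscoveryResult:
    """All outputs of one full discovery run."""

    candidates: pd.DataFrame
    filter_report: Dict[str, int]
    flagged_tissues: Set[str]
    analysed_tissues: List[str]
    eqtl_tables: Dict[str, pd.DataFrame]
    within: List[pd.DataFrame]
    cross: pd.DataFrame
    ledger: pd.DataFrame

    @property
    def within_combined(self) -> pd.DataFrame:
        hits = [t for t in self.within if len(t)]
        return pd.concat(hits, ignore_index=True) if hits else pd.DataFrame()

    @property
    def dual_pairs(self) -> Set[Tuple[str, str]]:
        de = self.ledger[self.ledger["dual_evidence"]] if len(self.ledger) else self.ledger
        return set(zip(de["tf"], de["gene"])) if len(de) else set()

    def multi_tissue_share(self) -> Tuple[int, int]:
        """(pairs supported by >1 tissue, pairs supported by >=1 tissue)."""
        if not len(self.ledger):
            return 0, 0
        tissue_backed = self.ledger[self.ledger["n_tissues"] >= 1]
        return int((tissue_backed["n_tissues"] > 1).sum()), int(len(tissue_backed))


def run_discovery(
    study: SyntheticStudy,
    maf_threshold: float = 0.05,
    fdr: float = 0.05,
    cis_window: float = 1e6,
    celltype_variance_threshold: float = 0.04,
    n_tissue_clusters: int | None = None,
) -> DiscoveryResult:
    """Run the complete discovery pipeline on a study.

    ``n_tissue_clusters`` optionally restricts the within-tissue analyses to
    representative tissues (one per expression cluster, largest sample size
    first); by default every non-flagged tissue is analysed.
    """
    candidates, report = build_candidates(
        study.genotypes, study.credible_sets, study.annotations, study.fetch,
        maf_threshold=maf_threshold,
    )
    flagged = flag_celltype_variance(study.xcell_scores, threshold=celltype_variance_threshold)
    if n_tissue_clusters is not None:
        median_tpm = pd.DataFrame(
            {t.tissue: t.median_tpm() for t in study.tissues}
        ).T
        sizes = {t.tissue: t.n_samples for t in study.tissues}
        analysed = select_tissues(median_tpm, sizes, k=n_tissue_clusters, excluded=flagged)
    else:
        analysed = [t.tissue for t in study.tissues if t.tissue not in flagged]
    if flagged:
        logger.info("tissues excluded for cell-type variance: %s", sorted(flagged))

    from .interactions import normalized_expression

    eqtl_tables: Dict[str, pd.DataFrame] = {}
    within: List[pd.DataFrame] = []
    meff_cache: Dict = {}
    for tname in analysed:
        tis = study.tissue(tname)
        norm_expr = normalized_expression(tis, set(candidates["gene"]))
        eqtl_tables[tname] = call_eqtls(study, tis, candidates, fdr=fdr, norm_expr=norm_expr)
        for tf in study.tf_ids:
            within.append(
                within_tissue_discovery(
                    candidates, study, tis, tf, fdr=fdr,
                    eqtl_table=eqtl_tables[tname], cis_window=cis_window,
                    norm_expr=norm_expr, meff_cache=meff_cache,
                )
            )

    afc_tab = afc_table(study, candidates)
    genes = sorted(set(candidates["gene"]))
    cross = cross_tissue_discovery(
        candidates, afc_tab,
        tf_levels_by_tissue(study, "expression"), study.genotypes,
        mode="expression", fdr=fdr, gene_expressed=expressed_mask(study, genes),
    )
    ledger = build_dual_evidence(within, cross)
    return DiscoveryResult(
        candidates=candidates, filter_report=report, flagged_tissues=flagged,
        analysed_tissues=analysed, eqtl_tables=eqtl_tables, within=within,
        cross=cross, ledger=ledger,
    )


def run_enrichment(
    study: SyntheticStudy,
    result: DiscoveryResult,
    n_perm: int = 10_000,
    seed: int = 0,
) -> Dict[str, EnrichmentResult]:
    """ChIP/motif overlap and ASB enrichment of the dual-evidence set."""
    pairs = result.dual_pairs
    out: Dict[str, EnrichmentResult] = {}
    if not pairs:
        logger.warning("no dual-evidence pairs; enrichment skipped")
        return out
    out["chip"] = overlap_enrichment(
        pairs, result.candidates, annotated_variants(result.candidates, "peak"),
        n_perm=n_perm, seed=seed,
    )
    out["motif"] = overlap_enrichment(
        pairs, result.candidates, annotated_variants(result.candidates, "motif"),
        n_perm=n_perm, seed=seed + 1,
    )
    out["asb_any"] = asb_enrichment(
        pairs, result.candidates, study.asb_table, mode="unmatched",
        n_perm=n_perm, seed=seed + 2,
    )
    out["asb_matched"] = asb_enrichment(
        pairs, result.candidates, study.asb_table, mode="matched",
        n_perm=n_perm, seed=seed + 3,
    )
    return out


def recovery_metrics(study: SyntheticStudy, result: DiscoveryResult) -> Dict[str, float]:
    """Sensitivity and observed FDR of the dual-evidence set against truth."""
    truth = study.truth.true_pairs
    found = result.dual_pairs
    tp = len(found & truth)
    return {
        "n_truth": len(truth),
        "n_found": len(found),
        "true_positives": tp,
        "sensitivity": tp / len(truth) if truth else float("nan"),
        "fdr": (len(found) - tp) / len(found) if found else 0.0,
    }
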