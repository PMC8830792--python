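"""Dual-evidence TF-eQTL set construction and Fisher overlap analyses.

A (TF, gene) interaction is retained as high-confidence when supported by at
least two lines of expression-based evidence: two within-tissue analyses, or
the cross-tissue expression correlation plus at least one tissue.
Protein-based correlations are recorded but never counted as evidence.
The resulting ledger is then intersected with external gene/pair sets —
regulons, gene-by-environment genes, GWAS colocalizations — via Fisher's
exact tests against an explicit background universe, with an LD r^2 filter
linking TF-eQTL and colocalization lead variants.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix

logger = logging.getLogger(__name__)

CROSS_SOURCE = "cross-expression"


def build_dual_evidence(
    within_results: Sequence[pd.DataFrame],
    cross_results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Evidence ledger over (TF, gene) pairs.

    ``within_results`` are per-(tissue, TF) result tables with a boolean
    ``pass`` column; ``cross_results`` the cross-tissue table (only rows
    with mode 'expression' count as evidence).  The ledger lists supporting
    sources (tissue names and/or 'cross-expression'), the top variant per
    source, and the dual-evidence flag.  Construction is idempotent and
    independent of input order.
    """
    sources: Dict[Tuple[str, str], Set[str]] = {}
    variants: Dict[Tuple[str, str], Set[str]] = {}
    for table in within_results:
        hits = table[table["pass"]] if len(table) else table
        for _, row in hits.iterrows():
            key = (row["tf"], row["gene"])
            sources.setdefault(key, set()).add(row["tissue"])
            variants.setdefault(key, set()).add(row["variant"])
    if cross_results is not None and len(cross_results):
        hits = cross_results[cross_results["pass"] & (cross_results["mode"] == "expression")]
        for _, row in hits.iterrows():
            key = (row["tf"], row["gene"])
            sources.setdefault(key, set()).add(CROSS_SOURCE)
            variants.setdefault(key, set()).add(row["variant"])
    rows = []
    for (tf, gene) in sorted(sources):
        src = sources[(tf, gene)]
        tissues = src - {CROSS_SOURCE}
        dual = len(tissues) >= 2 or (CROSS_SOURCE in src and len(tissues) >= 1)
        rows.append(
            {
                "tf": tf,
                "gene": gene,
                "sources": ",".join(sorted(src)),
                "n_tissues": len(tissues),
                "cross_tissue": CROSS_SOURCE in src,
                "variants": ",".join(sorted(variants[(tf, gene)])),
                "dual_evidence": dual,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["tf", "gene", "sources", "n_tissues", "cross_tissue", "variants", "dual_evidence"],
    )


@dataclass(frozen=True)
class OverlapTest:
    """2x2 membership table with Fisher's exact test."""

    a: int  # in both sets
    b: int  # in A only
    c: int  # in B only
    d: int  # in neither
    odds_ratio: float
    p: float
    flagged: bool  # zero cell: OR is 0 or infinite

    @property
    def table(self) -> List[List[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def fisher_overlap(set_a: Set, set_b: Set, universe: Set) -> OverlapTest:
    """Fisher's exact test of joint membership against a background universe."""
    if not universe:
        raise ValueError("empty universe")
    extra = (set_a | set_b) - set(universe)
    if extra:
        raise ValueError(f"{len(extra)} members outside the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    return _fisher_from_cells(a, b, c, d)


def _fisher_from_cells(a: int, b: int, c: int, d: int) -> OverlapTest:
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if b == 0 or c == 0:
        orr = np.inf if a * d > 0 else (0.0 if a == 0 else np.inf)
        flagged = True
    else:
        orr = (a * d) / (b * c)
        flagged = a == 0 or d == 0
    return OverlapTest(a=a, b=b, c=c, d=d, odds_ratio=float(orr), p=p, flagged=flagged)


def regulon_enrichment(
    ledger: pd.DataFrame,
    regulons: Mapping[str, Mapping[str, Set[str]]],
    universe: Set[str],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(TF, regulon-type) overlap tests plus pooled per-type tests.

    ``regulons`` maps regulon type -> TF -> target gene set; the 'any' type,
    if absent, is added as the union of the others.  Per TF, the dual-
    evidence genes of that TF are tested against the regulon inside the
    gene universe; the pooled table sums the 2x2 cells across TFs per type.
    TFs without a regulon are skipped.
    """
    regulons = {k: dict(v) for k, v in regulons.items()}
    if "any" not in regulons:
        base = [t for t in regulons if t != "any"]
        tfs = set().union(*(set(regulons[t]) for t in base))
        regulons["any"] = {
            tf: set().union(*(regulons[t].get(tf, set()) for t in base)) for tf in tfs
        }
    de = ledger[ledger["dual_evidence"]]
    genes_by_tf = {tf: set(grp["gene"]) & universe for tf, grp in de.groupby("tf")}
    per_rows = []
    pooled_rows = []
    for rtype, by_tf in regulons.items():
        cells = np.zeros(4, dtype=np.int64)
        for tf, tf_genes in sorted(genes_by_tf.items()):
            reg = by_tf.get(tf, set()) & universe
            if not reg:
                logger.info("TF %s absent from %s regulons; skipped", tf, rtype)
                continue
            test = fisher_overlap(tf_genes, reg, universe)
            cells += [test.a, test.b, test.c, test.d]
            per_rows.append(
                {"regulon_type": rtype, "tf": tf, "a": test.a, "b": test.b,
                 "c": test.c, "d": test.d, "odds_ratio": test.odds_ratio, "p": test.p}
            )
        if cells.sum():
            pooled = _fisher_from_cells(*map(int, cells))
            pooled_rows.append(
                {"regulon_type": rtype, "a": pooled.a, "b": pooled.b, "c": pooled.c,
                 "d": pooled.d, "odds_ratio": pooled.odds_ratio, "p": pooled.p}
            )
    return pd.DataFrame(per_rows), pd.DataFrame(pooled_rows)


def ld_r2(dosage_a: Sequence[float], dosage_b: Sequence[float]) -> float:
    """Squared Pearson correlation of dosages (LD r^2), pairwise-complete.

    Undefined (NaN) when either variant is monomorphic among shared
    individuals.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.size != b.size:
        raise ValueError("dosage vectors must cover the same individuals")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def gxe_overlap(ledger_genes: Set[str], gxe_genes: Set[str], universe: Set[str]) -> OverlapTest:
    """Overlap of dual-evidence TF-eQTL genes with gene-by-environment genes."""
    test = fisher_overlap(set(ledger_genes), set(gxe_genes) & set(universe), set(universe))
    if test.d == 0:
        logger.warning("degenerate universe: no genes outside either set")
    return test


def gwas_coloc_overlap(
    ledger: pd.DataFrame,
    coloc_table: pd.DataFrame,
    geno: GenotypeMatrix,
    universe_genes: Set[str],
    tissue_universe: Set[str] | None = None,
    rcp_min: float = 0.5,
    r2_min: float = 0.4,
) -> Tuple[OverlapTest, OverlapTest, pd.DataFrame]:
    """GWAS-colocalization overlap of the dual-evidence TF-eQTL set.

    Colocalization rows are filtered to regional conditional probability
    strictly above ``rcp_min``.  Two Fisher tests are returned: gene-level
    (TF-eQTL gene vs gene with a colocalized eQTL in any tissue, over
    ``universe_genes``) and eQTL-level (same (gene, tissue) unit, over
    universe genes x analysed tissues).  The third output lists matched
    (TF-eQTL, colocalization) rows in the same tissue with the LD r^2
    between top TF-eQTL variant and colocalization lead variant; rows with
    r^2 strictly above ``r2_min`` are marked kept, rows whose lead variant
    is absent from the genotypes keep a flag instead of a verdict.
    """
    coloc = coloc_table[coloc_table["rcp"] > rcp_min]
    de = ledger[ledger["dual_evidence"]]
    de_genes = set(de["gene"]) & universe_genes
    coloc_genes = set(coloc["gene"]) & universe_genes
    gene_test = fisher_overlap(de_genes, coloc_genes, universe_genes)

    if tissue_universe is None:
        tissue_universe = set(coloc["tissue"])
    de_pairs = set()
    for _, row in de.iterrows():
        for src in row["sources"].split(","):
            if src != "cross-expression" and src in tissue_universe:
                de_pairs.add((row["gene"], src))
    coloc_pairs = {
        (g, t) for g, t in zip(coloc["gene"], coloc["tissue"])
        if g in universe_genes and t in tissue_universe
    }
    pair_universe = {(g, t) for g in universe_genes for t in sorted(tissue_universe)}
    pair_test = fisher_overlap(de_pairs, coloc_pairs, pair_universe)

    rows = []
    known = set(geno.variant_ids)
    for _, crow in coloc.iterrows():
        hits = de[de["gene"] == crow["gene"]]
        for _, lrow in hits.iterrows():
            if crow["tissue"] not in lrow["sources"].split(","):
                continue
            for top in lrow["variants"].split(","):
                if crow["lead_variant"] not in known or top not in known:
                    rows.append(
                        {"tf": lrow["tf"], "gene": lrow["gene"], "tissue": crow["tissue"],
                         "trait": crow["trait"], "rcp": crow["rcp"],
                         "tf_eqtl_variant": top, "lead_variant": crow["lead_variant"],
                         "r2": np.nan, "kept": False, "unresolved": True}
                    )
                    continue
                r2 = ld_r2(geno.dosage(top), geno.dosage(crow["lead_variant"]))
                rows.append(
                    {"tf": lrow["tf"], "gene": lrow["gene"], "tissue": crow["tissue"],
                     "trait": crow["trait"], "rcp": crow["rcp"],
                     "tf_eqtl_variant": top, "lead_variant": crow["lead_variant"],
                     "r2": r2, "kept": bool(np.isfinite(r2) and r2 > r2_min),
                     "unresolved": False}
                )
    matches = pd.DataFrame(
        rows, columns=["tf", "gene", "tissue", "trait", "rcp", "tf_eqtl_variant",
                       "lead_variant", "r2", "kept", "unresolved"],
    )
    return gene_test, pair_test, matches
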