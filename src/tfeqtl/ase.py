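"""Conditional allele-specific expression in a TF-knockdown experiment.

If a TF regulates an eQTL, changing the TF's level should change the
allelic imbalance of the target gene.  Coding-SNP allelic read counts,
pooled per condition (knockdown vs control), are compared with Fisher's
exact test; a low p-value means the alleles are expressed at different
ratios in the two conditions.  Validation of a TF-eQTL additionally
requires the cell line to be heterozygous for an implicated regulatory
variant — a gene cannot show conditional ASE driven by an eQTL it does not
carry in heterozygous form.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def filter_sites(
    ref: int,
    alt: int,
    other: int = 0,
    min_total: int = 60,
    min_frac: float = 0.05,
    max_other: float = 0.05,
) -> bool:
    """Coverage/allele-balance filter for one coding site (condition-pooled).

    Pass iff total reads > ``min_total``, each of the reference and
    alternate fractions > ``min_frac``, and the fraction of other alleles
    < ``max_other`` (all strict, fractions over total reads including
    others).
    """
    if min(ref, alt, other) < 0:
        raise ValueError("counts must be non-negative")
    total = ref + alt + other
    if total <= min_total:
        return False
    return (
        ref / total > min_frac
        and alt / total > min_frac
        and other / total < max_other
    )


def conditional_ase_test(
    kd_counts: Tuple[int, int], ctrl_counts: Tuple[int, int]
) -> float:
    """Two-sided Fisher exact p for condition x allele read counts.

    Reads are pooled within condition.  A zero margin (an allele or a
    condition with no reads) is uninformative and returns p = 1.
    """
    table = np.array([list(kd_counts), list(ctrl_counts)], dtype=np.int64)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        logger.warning("zero margin in ASE table %s; p set to 1", table.tolist())
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass(frozen=True)
class GeneVerdict:
    """Validation verdict for one TF-eQTL gene in the knockdown assay."""

    gene: str
    variant: str
    p: float
    heterozygous: bool
    verdict: str  # validated | testable-not-validated | untestable


def classify_validation(
    counts: pd.DataFrame,
    tf_eqtl_genes: Iterable[str],
    het_genes: Mapping[str, bool],
    alpha: float = 0.05,
    kd_label: str = "knockdown",
    ctrl_label: str = "control",
    min_total: int = 60,
    min_frac: float = 0.05,
    max_other: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-gene validation verdicts for a TF-eQTL gene set.

    ``counts`` has columns gene, variant, condition, ref_count, alt_count,
    other_count (one row per coding site per condition).  Sites are filtered
    on condition-pooled counts; when a gene has several passing coding SNPs
    the highest-coverage one is used.  Verdicts: ``validated`` (heterozygous
    regulatory variant and p < alpha), ``testable-not-validated``
    (heterozygous, p >= alpha), ``untestable`` (no heterozygous regulatory
    variant — significance without one does not count as validation).
    Genes without a passing site are excluded with a reason row.
    """
    nominal_alpha = alpha
    rows = []
    for gene in sorted(set(tf_eqtl_genes)):
        sub = counts[counts["gene"] == gene]
        if sub.empty:
            rows.append((gene, "", np.nan, bool(het_genes.get(gene, False)), "no-coding-site"))
            continue
        best = None
        for variant, site in sub.groupby("variant"):
            pooled = site[["ref_count", "alt_count", "other_count"]].sum()
            if not filter_sites(
                int(pooled["ref_count"]), int(pooled["alt_count"]), int(pooled["other_count"]),
                min_total=min_total, min_frac=min_frac, max_other=max_other,
            ):
                continue
            cov = int(pooled.sum())
            if best is None or cov > best[1]:
                best = (variant, cov, site)
        if best is None:
            rows.append((gene, "", np.nan, bool(het_genes.get(gene, False)), "low-coverage"))
            continue
        variant, _, site = best
        kd = site[site["condition"] == kd_label][["ref_count", "alt_count"]].sum()
        ctrl = site[site["condition"] == ctrl_label][["ref_count", "alt_count"]].sum()
        p = conditional_ase_test(
            (int(kd["ref_count"]), int(kd["alt_count"])),
            (int(ctrl["ref_count"]), int(ctrl["alt_count"])),
        )
        rows.append((gene, variant, p, bool(het_genes.get(gene, False)), ""))
    out = pd.DataFrame(rows, columns=["gene", "variant", "p", "heterozygous", "note"])
    testable = out["note"] == ""
    if bh and testable.any():
        from .interactions import bh_adjust

        out.loc[testable, "p_adj"] = bh_adjust(out.loc[testable, "p"].to_numpy())
        crit = out.get("p_adj")
    else:
        out["p_adj"] = np.nan
        crit = out["p"]
    verdicts = []
    for i, row in out.iterrows():
        if row["note"]:
            verdicts.append("excluded")
        elif not row["heterozygous"]:
            verdicts.append("untestable")
        elif (crit[i] if bh else row["p"]) < nominal_alpha:
            verdicts.append("validated")
        else:
            verdicts.append("testable-not-validated")
    out["verdict"] = verdicts
    return out


def validation_summary(verdicts: pd.DataFrame) -> Dict[str, int]:
    """Counts of genes per verdict class."""
    return verdicts["verdict"].value_counts().to_dict()
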