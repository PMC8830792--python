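"""Expectation/observation enrichment statistics with permutation p-values.

TF-eQTL discovery tests many variants per gene, with LD among them, so a
naive per-variant enrichment test is miscalibrated.  Instead, for TF ``f``
and gene ``g`` with ``v_g`` tested variants of which ``o_fg`` carry the
annotation (ChIP-seq peak overlap, motif match, or allele-specific binding),
and annotation probability ``p_f`` among all tested variants,

    S_fg = o_fg - v_g * p_f

is the per-gene excess of annotated variants over expectation.  Per-TF
statistics average S_fg over that TF's significant genes, and the pooled
statistic is their gene-count-weighted mean — algebraically the plain mean
of all per-gene statistics.  A pooled statistic of 0.01 therefore reads as
one extra annotated variant per 100 TF-eQTL genes.

Significance comes from shuffling annotation flags across the tested
variant universe (independently per TF, since p_f is per-TF) and
recomputing the statistic; the two-sided p doubles the smaller exceedance
tail, counting ties as exceedances and adding one before dividing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneEnrichmentInput:
    """Observed vs expected annotation counts for one (TF, gene)."""

    gene: str
    tf: str
    v: int  # tested variants for the gene
    o: int  # of which annotated
    p: float  # annotation probability among all tested variants

    def __post_init__(self) -> None:
        if not (0 <= self.o <= self.v):
            raise ValueError("require 0 <= o <= v")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("require 0 <= p <= 1")


def gene_stat(inp: GeneEnrichmentInput) -> float:
    """Per-gene excess of annotated variants: o - v * p."""
    return inp.o - inp.v * inp.p


def tf_stat(inputs: Sequence[GeneEnrichmentInput]) -> Tuple[float, int]:
    """Mean per-gene statistic over one TF's genes; returns (S_f, |G_f|)."""
    if not inputs:
        raise ValueError("no genes for TF")
    return float(np.mean([gene_stat(i) for i in inputs])), len(inputs)


def pooled_stat(per_tf: Sequence[Tuple[float, int]]) -> float:
    """Gene-count-weighted mean of per-TF statistics.

    Equals the unweighted mean of all per-gene statistics pooled over
    (TF, gene) pairs.
    """
    if not per_tf:
        raise ValueError("empty input")
    s = np.array([s for s, _ in per_tf], dtype=float)
    w = np.array([n for _, n in per_tf], dtype=float)
    if np.any(w < 1):
        raise ValueError("each TF needs at least one gene")
    return float((s * w).sum() / w.sum())


def extra_overlaps_per_100_genes(s_pooled: float) -> float:
    """Interpretation of the pooled statistic: extra annotated variants per
    100 TF-eQTL genes."""
    return 100.0 * s_pooled


def permutation_test(
    observed: float,
    annotation_labels: Mapping[str, np.ndarray] | np.ndarray,
    recompute: Callable[[Mapping[str, np.ndarray] | np.ndarray], float],
    n_perm: int = 10_000,
    seed: int = 0,
    tail: str = "min-doubled",
) -> Tuple[np.ndarray, float]:
    """Annotation-shuffling permutation test.

    ``annotation_labels`` is a boolean flag array over the tested variant
    universe, or a dict of such arrays per TF; each permutation shuffles
    every array independently and calls ``recompute`` on the shuffled
    labels.  ``tail='min-doubled'`` doubles the smaller of the >= / <=
    exceedance counts (ties count as exceedances, +1, truncated at 1);
    ``tail='both-sum'`` counts |null| >= |observed| instead.
    """
    if n_perm < 100:
        logger.warning("n_perm = %d is very small for a permutation p-value", n_perm)
    rng = np.random.default_rng(seed)
    single = isinstance(annotation_labels, np.ndarray)
    labels = {"": annotation_labels} if single else dict(annotation_labels)
    labels = {k: np.asarray(v) for k, v in labels.items()}
    null = np.empty(n_perm)
    work = {k: v.copy() for k, v in labels.items()}
    for i in range(n_perm):
        for k in work:
            work[k] = rng.permutation(work[k])
        null[i] = recompute(work[""] if single else work)
    if tail == "min-doubled":
        n_hi = int(np.sum(null >= observed))
        n_lo = int(np.sum(null <= observed))
        p = 2.0 * (min(n_hi, n_lo) + 1) / n_perm
    elif tail == "both-sum":
        p = (int(np.sum(np.abs(null) >= abs(observed))) + 1) / (n_perm + 1)
    else:
        raise ValueError("tail must be 'min-doubled' or 'both-sum'")
    return null, float(min(p, 1.0))


@dataclass
class EnrichmentResult:
    """Pooled enrichment statistic with its permutation null."""

    s_pooled: float
    s_per_tf: Dict[str, Tuple[float, int]]
    s_per_gene: Dict[Tuple[str, str], float]
    null_stats: np.ndarray
    p_perm: float
    n_perm: int

    @property
    def extra_per_100_genes(self) -> float:
        return extra_overlaps_per_100_genes(self.s_pooled)


class _PooledStat:
    """Vectorized pooled statistic over per-TF gene/variant index structures."""

    def __init__(
        self,
        universe: List[str],
        gene_variants: Mapping[str, Sequence[str]],
        tf_genes: Mapping[str, Sequence[str]],
    ) -> None:
        self.universe = list(universe)
        pos = {v: i for i, v in enumerate(self.universe)}
        self.struct: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray, List[str]]] = {}
        self.n_genes_total = 0
        for tf, genes in tf_genes.items():
            genes = [g for g in genes if len(gene_variants.get(g, ())) > 0]
            if not genes:
                continue
            cat, offsets, v_g = [], [], []
            for g in genes:
                offsets.append(len(cat))
                vids = [pos[v] for v in gene_variants[g] if v in pos]
                cat.extend(vids)
                v_g.append(len(vids))
            if not cat:
                continue
            self.struct[tf] = (
                np.asarray(cat, dtype=np.intp),
                np.asarray(offsets, dtype=np.intp),
                np.asarray(v_g, dtype=float),
                genes,
            )
            self.n_genes_total += len(genes)
        if self.n_genes_total == 0:
            raise ValueError("no (TF, gene) units with tested variants")

    def per_gene(self, flags: Mapping[str, np.ndarray]) -> Dict[Tuple[str, str], float]:
        out = {}
        for tf, (cat, offsets, v_g, genes) in self.struct.items():
            f = np.asarray(flags[tf], dtype=float)
            p_f = f.mean()
            o = np.add.reduceat(f[cat], offsets) if len(cat) else np.zeros(0)
            s = o - v_g * p_f
            out.update({(tf, g): float(x) for g, x in zip(genes, s)})
        return out

    def pooled(self, flags: Mapping[str, np.ndarray]) -> float:
        total = 0.0
        for tf, (cat, offsets, v_g, genes) in self.struct.items():
            f = np.asarray(flags[tf], dtype=float)
            p_f = f.mean()
            o = np.add.reduceat(f[cat], offsets)
            total += float((o - v_g * p_f).sum())
        return total / self.n_genes_total


def _result_from_stat(
    stat: _PooledStat,
    flags: Dict[str, np.ndarray],
    n_perm: int,
    seed: int,
    tail: str,
) -> EnrichmentResult:
    observed = stat.pooled(flags)
    per_gene = stat.per_gene(flags)
    per_tf: Dict[str, Tuple[float, int]] = {}
    for tf, (_, _, _, genes) in stat.struct.items():
        vals = [per_gene[(tf, g)] for g in genes]
        per_tf[tf] = (float(np.mean(vals)), len(genes))
    null, p = permutation_test(observed, flags, stat.pooled, n_perm=n_perm, seed=seed, tail=tail)
    return EnrichmentResult(
        s_pooled=observed, s_per_tf=per_tf, s_per_gene=per_gene,
        null_stats=null, p_perm=p, n_perm=n_perm,
    )


def overlap_enrichment(
    result_pairs: Set[Tuple[str, str]],
    candidates: pd.DataFrame,
    annotated: Mapping[str, Set[str]],
    n_perm: int = 10_000,
    seed: int = 0,
    tail: str = "min-doubled",
) -> EnrichmentResult:
    """TF-binding-site overlap enrichment of a TF-eQTL result set.

    ``result_pairs`` are significant (TF, gene) interactions; ``candidates``
    is the tested eVariant-eGene table (defines per-gene tested variants and
    the variant universe); ``annotated[tf]`` is the set of universe variants
    carrying the annotation for that TF (peak overlap or motif match).
    """
    universe = sorted(set(candidates["variant"]))
    gene_variants = {g: sorted(set(grp["variant"])) for g, grp in candidates.groupby("gene")}
    tf_genes: Dict[str, List[str]] = {}
    for tf, gene in sorted(result_pairs):
        tf_genes.setdefault(tf, []).append(gene)
    stat = _PooledStat(universe, gene_variants, tf_genes)
    flags = {
        tf: np.array([v in annotated.get(tf, set()) for v in universe], dtype=bool)
        for tf in stat.struct
    }
    return _result_from_stat(stat, flags, n_perm, seed, tail)


def asb_enrichment(
    result_pairs: Set[Tuple[str, str]],
    candidates: pd.DataFrame,
    asb_table: pd.DataFrame,
    mode: str = "matched",
    n_perm: int = 10_000,
    seed: int = 0,
    tail: str = "min-doubled",
) -> EnrichmentResult:
    """Allele-specific-binding enrichment of a TF-eQTL result set.

    The variant universe is restricted to candidates assayed in the ASB
    table; per-gene tested-variant counts use only assayed variants, and
    genes with none drop out of the denominator.  ``mode='unmatched'`` uses
    a TF-agnostic ASB probability over genes with any TF-eQTL;
    ``mode='matched'`` uses per-TF ASB flags pooled per TF.
    """
    assayed = set(asb_table["variant"])
    cand = candidates[candidates["variant"].isin(assayed)]
    if cand.empty:
        raise ValueError("no candidate variants assayed for ASB")
    universe = sorted(set(cand["variant"]))
    gene_variants = {g: sorted(set(grp["variant"])) for g, grp in cand.groupby("gene")}
    hit = asb_table[asb_table["asb"].astype(bool)]
    if mode == "unmatched":
        any_asb = set(hit["variant"])
        genes_any = sorted({g for _, g in result_pairs})
        stat = _PooledStat(universe, gene_variants, {"any": genes_any})
        flags = {"any": np.array([v in any_asb for v in universe], dtype=bool)}
    elif mode == "matched":
        tf_genes: Dict[str, List[str]] = {}
        for tf, gene in sorted(result_pairs):
            tf_genes.setdefault(tf, []).append(gene)
        per_tf_asb = {tf: set(grp["variant"]) for tf, grp in hit.groupby("tf")}
        stat = _PooledStat(universe, gene_variants, tf_genes)
        flags = {
            tf: np.array([v in per_tf_asb.get(tf, set()) for v in universe], dtype=bool)
            for tf in stat.struct
        }
    else:
        raise ValueError("mode must be 'unmatched' or 'matched'")
    return _result_from_stat(stat, flags, n_perm, seed, tail)
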