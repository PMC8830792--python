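"""Candidate regulatory-variant selection.

Variants enter the TF-eQTL analysis only if they (1) are common, (2) fall in
a fine-mapping credible set for some eGene, (3) overlap a TF ChIP-seq peak,
and (4) match a TF binding motif.  The intersection, expanded through
credible-set gene links, yields the eVariant-eGene candidate pairs that all
downstream discovery operates on.

Coordinate conventions are fixed and unit-tested: variant positions are
1-based (VCF), peak intervals are 0-based half-open (BED), and a position p
overlaps [s, e) iff s < p <= e.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import AnnotationSet, GenomeFetcher, GenotypeMatrix

logger = logging.getLogger(__name__)

IUPAC_CLASSES: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
# letters degenerate to three or four nucleotides, trimmed from motif ends
_HIGH_DEGENERACY = set("BDHVN")


def maf_filter(geno: GenotypeMatrix, threshold: float = 0.05) -> Set[str]:
    """Variant ids with minor allele frequency >= threshold.

    Missing dosages are excluded from the allele-frequency denominator; a
    variant with all genotypes missing is excluded with a warning.
    """
    if not (0 < threshold < 0.5):
        raise ValueError("threshold must be in (0, 0.5)")
    n_obs = np.sum(~np.isnan(geno.dosages), axis=0)
    all_missing = n_obs == 0
    if np.any(all_missing):
        logger.warning("%d variants with all-missing genotypes excluded", all_missing.sum())
    maf = geno.maf().to_numpy()
    keep = ~all_missing & (maf >= threshold)
    return set(np.asarray(geno.variant_ids)[keep])


class UntestableMotif(ValueError):
    """Raised when a consensus motif is empty after end-trimming."""


@dataclass(frozen=True)
class MotifPatterns:
    """Trimmed forward / reverse-complement scan patterns for one motif."""

    forward: str
    revcomp: str
    length: int  # trimmed length

    @property
    def forward_re(self) -> re.Pattern:
        return re.compile(_to_regex(self.forward))

    @property
    def revcomp_re(self) -> re.Pattern:
        return re.compile(_to_regex(self.revcomp))


def _to_regex(consensus: str) -> str:
    parts = []
    for letter in consensus:
        cls = IUPAC_CLASSES[letter]
        parts.append(cls if len(cls) == 1 else f"[{cls}]")
    return "".join(parts)


def iupac_to_patterns(consensus: str) -> MotifPatterns:
    """Trim low-confidence ends of an IUPAC consensus and build scan patterns.

    Letters degenerate to three or four nucleotides (B, D, H, V, N) are
    stripped iteratively from each end until a <=2-fold letter is reached; an
    interior degenerate letter shielded by a confident one is kept.  The
    reverse-complement pattern is built from the reverse complement of the
    trimmed consensus.  A motif empty after trimming is signalled distinctly
    via :class:`UntestableMotif`.
    """
    s = consensus.strip().upper()
    bad = set(s) - set(IUPAC_CLASSES)
    if bad:
        raise ValueError(f"non-IUPAC letters in consensus: {sorted(bad)}")
    lo, hi = 0, len(s)
    while lo < hi and s[lo] in _HIGH_DEGENERACY:
        lo += 1
    while hi > lo and s[hi - 1] in _HIGH_DEGENERACY:
        hi -= 1
    trimmed = s[lo:hi]
    if not trimmed:
        raise UntestableMotif(f"motif {consensus!r} empty after trimming")
    revcomp = trimmed.translate(_COMPLEMENT)[::-1]
    return MotifPatterns(forward=trimmed, revcomp=revcomp, length=len(trimmed))


def motif_match(
    variant: Tuple[str, int, str, str],
    fetch: GenomeFetcher,
    patterns: MotifPatterns,
) -> Tuple[bool, bool]:
    """Scan the +/- (L-1) window around a SNV for a motif, per allele.

    ``variant`` is (chrom, 1-based pos, ref, alt).  For each allele the
    window of length 2L - 1 centered on the variant, with that allele
    substituted at the center, is scanned for any occurrence of the forward
    or reverse-complement pattern.  Windows truncated by a contig edge are
    scanned as available.  Only SNVs are supported; indels return
    (False, False) with a warning.
    """
    chrom, pos, ref, alt = variant
    if len(ref) != 1 or len(alt) != 1:
        logger.warning("skipping non-SNV %s:%d %s>%s in motif matching", chrom, pos, ref, alt)
        return (False, False)
    L = patterns.length
    start = pos - 1 - (L - 1)  # 0-based window start
    window = fetch(chrom, max(0, start), pos - 1 + L).upper()
    center = (pos - 1) - max(0, start)
    fwd, rc = patterns.forward_re, patterns.revcomp_re
    out = []
    for allele in (ref, alt):
        seq = window[:center] + allele.upper() + window[center + 1:]
        out.append(bool(fwd.search(seq) or rc.search(seq)))
    return (out[0], out[1])


def _peak_trees(peaks: Mapping[str, Sequence[Tuple[str, int, int]]]) -> Dict[str, Dict[str, IntervalTree]]:
    trees: Dict[str, Dict[str, IntervalTree]] = {}
    for tf, ivs in peaks.items():
        per_chrom: Dict[str, IntervalTree] = {}
        for chrom, s, e in ivs:
            per_chrom.setdefault(chrom, IntervalTree()).addi(s, e)
        trees[tf] = per_chrom
    return trees


def peak_overlap(
    variants: pd.DataFrame,
    annotations: AnnotationSet,
) -> Dict[str, Set[str]]:
    """TFs whose merged peak union covers each variant position.

    ``variants`` needs columns chrom and pos (1-based).  A position p
    overlaps a 0-based half-open interval [s, e) iff s < p <= e, i.e. the
    1-based base p sits at 0-based index p - 1 inside the interval.
    """
    trees = _peak_trees(annotations.peaks)
    out: Dict[str, Set[str]] = {vid: set() for vid in variants.index}
    for vid, row in variants.iterrows():
        p0 = int(row["pos"]) - 1  # 0-based index of the base
        for tf, per_chrom in trees.items():
            tree = per_chrom.get(row["chrom"])
            if tree is not None and tree.overlaps_point(p0):
                out[vid].add(tf)
    return out


def motif_tf_sets(
    variants: pd.DataFrame,
    fetch: GenomeFetcher,
    annotations: AnnotationSet,
) -> Dict[str, Set[str]]:
    """TFs whose motif matches either allele of each variant."""
    compiled = {}
    for tf, consensus in annotations.motifs.items():
        try:
            compiled[tf] = iupac_to_patterns(consensus)
        except UntestableMotif:
            logger.warning("motif for %s untestable after trimming; skipped", tf)
    out: Dict[str, Set[str]] = {vid: set() for vid in variants.index}
    for vid, row in variants.iterrows():
        var = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        for tf, pat in compiled.items():
            ref_m, alt_m = motif_match(var, fetch, pat)
            if ref_m or alt_m:
                out[vid].add(tf)
    return out


def build_candidates(
    geno: GenotypeMatrix,
    credible_sets: pd.DataFrame,
    annotations: AnnotationSet,
    fetch: GenomeFetcher,
    maf_threshold: float = 0.05,
    strict_same_tf: bool = False,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Intersect the four filters and expand variants to eVariant-eGene pairs.

    Returns the candidate-pair table (one row per variant-gene link, with
    the TF sets implied by peak overlap and motif match and the credible-set
    source tissues) and a per-filter count report in the style of a variant
    annotation summary table.  With ``strict_same_tf`` the peak and motif
    criteria must implicate at least one common TF; by default they are
    independent ("at least one TF" each).
    """
    universe = list(geno.variant_ids)
    maf_pass = maf_filter(geno, maf_threshold)
    in_credible = set(credible_sets["variant"])
    common = geno.variants.loc[[v for v in universe if v in maf_pass]]
    peak_sets = peak_overlap(common, annotations)
    motif_sets = motif_tf_sets(common, fetch, annotations)

    def _passes(vid: str) -> bool:
        if vid not in maf_pass or vid not in in_credible:
            return False
        p, m = peak_sets[vid], motif_sets[vid]
        if strict_same_tf:
            return bool(p & m)
        return bool(p) and bool(m)

    kept = [v for v in universe if _passes(v)]
    report = {
        "all": len(maf_pass),
        "credible_set": len(maf_pass & in_credible),
        "chip_peak": sum(bool(peak_sets[v]) for v in maf_pass),
        "motif_match": sum(bool(motif_sets[v]) for v in maf_pass),
        "intersection": len(kept),
    }
    links = credible_sets[credible_sets["variant"].isin(kept)]
    rows = []
    for (vid, gene), grp in links.groupby(["variant", "gene"], sort=True):
        rows.append(
            {
                "variant": vid,
                "gene": gene,
                "peak_tfs": ",".join(sorted(peak_sets[vid])),
                "motif_tfs": ",".join(sorted(motif_sets[vid])),
                "source_tissues": ",".join(sorted(set(grp["tissue"]))),
            }
        )
    candidates = pd.DataFrame(rows, columns=["variant", "gene", "peak_tfs", "motif_tfs", "source_tissues"])
    if candidates.empty:
        logger.warning("no variants survived the filter intersection")
    return candidates, report


def filter_percentages(report: Mapping[str, int], total_key: str = "all") -> Dict[str, float]:
    """Per-filter share of the common-variant universe, in percent.

    Rounded to the nearest whole percent, the convention used when such
    annotation tables are reported.
    """
    total = report[total_key]
    return {
        k: round(100.0 * v / total) for k, v in report.items() if k != total_key
    }
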