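"""Shared in-memory containers for the TF-eQTL analysis pipeline.

The pipeline moves four kinds of data around: genotypes (individuals x
variants alternate-allele dosages), per-tissue expression (genes x samples
TPM plus covariates), per-TF functional annotation (ChIP-seq peak intervals
and IUPAC consensus motifs), and simulation ground truth.  These are thin
dataclasses over numpy/pandas objects; all heavier logic lives in the stage
modules.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd


class ModelKind(str, Enum):
    """Mechanistic cartoon for how an eQTL allele changes TF-driven output.

    ``affinity_change``: both alleles carry the TF site but with different
    dissociation scales; the allelic fold change vanishes at zero TF and at
    saturation (the non-monotonic "hill").
    ``additive_site``: the alternate allele gains a second, independent TF
    site whose output adds to the shared site.
    ``multiplicative_site``: the extra site amplifies the shared site's
    output multiplicatively.  Both site-gain models are monotone in TF level.
    """

    affinity_change = "affinity_change"
    additive_site = "additive_site"
    multiplicative_site = "multiplicative_site"


@dataclass(frozen=True)
class OccupancyModel:
    """Saturating TF-occupancy dose-response model for one regulatory variant.

    Per-allele transcriptional output at TF level ``T`` is

        basal_rate + (max_rate - basal_rate) * T / (T + K_allele)

    (for ``affinity_change``), a Michaelis-Menten-style curve: ``K_allele``
    is the TF level at half-maximal occupancy of that allele's binding site.
    Units of ``T`` and ``K`` are arbitrary but shared; output is transcripts
    per allele in arbitrary units.
    """

    basal_rate: float = 1.0
    max_rate: float = 9.0
    K_ref: float = 10.0
    K_alt: float = 1.0
    model_kind: ModelKind = ModelKind.affinity_change

    def __post_init__(self) -> None:
        if self.basal_rate < 0:
            raise ValueError("basal_rate must be >= 0")
        if self.max_rate <= self.basal_rate:
            raise ValueError("max_rate must exceed basal_rate")
        if self.K_ref <= 0 or self.K_alt <= 0:
            raise ValueError("dissociation scales must be positive")

    def _occ(self, T: np.ndarray, K: float) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return T / (T + K)

    def allele_output(self, T, allele: str) -> np.ndarray:
        """Transcriptional output of one allele ("ref" or "alt") at TF level T."""
        T = np.asarray(T, dtype=float)
        if np.any(T < 0):
            raise ValueError("TF level must be non-negative")
        span = self.max_rate - self.basal_rate
        shared = self.basal_rate + span * self._occ(T, self.K_ref)
        if self.model_kind == ModelKind.affinity_change:
            if allele == "ref":
                return shared
            return self.basal_rate + span * self._occ(T, self.K_alt)
        extra = self._occ(T, self.K_alt)
        if allele == "ref":
            return shared
        if self.model_kind == ModelKind.additive_site:
            return shared + span * extra
        return shared * (1.0 + extra)

    def log2_afc(self, T) -> np.ndarray:
        """log2 allelic fold change (alt over ref output) at TF level T."""
        with np.errstate(divide="ignore"):
            return np.log2(self.allele_output(T, "alt") / self.allele_output(T, "ref"))


@dataclass
class GenotypeMatrix:
    """Alternate-allele dosages (0/1/2) for individuals x variants.

    ``dosages`` is float to allow NaN for missing genotypes.  ``variants``
    is indexed by variant id with columns chrom, pos (1-based), ref, alt,
    maf (realized minor allele frequency).
    """

    dosages: np.ndarray
    individuals: List[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.individuals), len(self.variants)):
            raise ValueError("dosage matrix shape does not match labels")

    @property
    def variant_ids(self) -> List[str]:
        return list(self.variants.index)

    def dosage(self, variant_id: str, individuals: Sequence[str] | None = None) -> np.ndarray:
        col = self.dosages[:, self.variants.index.get_loc(variant_id)]
        if individuals is None:
            return col
        idx = pd.Index(self.individuals).get_indexer(individuals)
        if np.any(idx < 0):
            raise KeyError("unknown individual id")
        return col[idx]

    def maf(self) -> pd.Series:
        """Minor allele frequency from dosages; missing entries excluded."""
        n_obs = np.sum(~np.isnan(self.dosages), axis=0)
        total = np.nansum(self.dosages, axis=0)
        af = np.where(n_obs > 0, total / (2.0 * np.maximum(n_obs, 1)), np.nan)
        return pd.Series(np.minimum(af, 1.0 - af), index=self.variants.index, name="maf")


@dataclass
class TissueExpression:
    """One tissue's expression: genes x samples TPM and per-sample covariates.

    Sample ids are individual ids (one sample per individual per tissue).
    ``normalized`` caches rank-based inverse-normal values when computed.
    """

    tissue: str
    tpm: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.covariates) and not self.covariates.index.equals(self.tpm.columns):
            self.covariates = self.covariates.reindex(self.tpm.columns)

    @property
    def samples(self) -> List[str]:
        return list(self.tpm.columns)

    @property
    def n_samples(self) -> int:
        return self.tpm.shape[1]

    def median_tpm(self) -> pd.Series:
        return self.tpm.median(axis=1)


Interval = Tuple[str, int, int]  # chrom, start, end; 0-based half-open


@dataclass
class AnnotationSet:
    """Per-TF ChIP-seq peak intervals and IUPAC consensus motifs.

    Peaks are 0-based half-open and are merged to a union per TF on
    construction (mirrors pooling of replicate peak files).  Motif strings
    use the 15-letter IUPAC nucleotide alphabet.
    """

    peaks: Dict[str, List[Interval]] = field(default_factory=dict)
    motifs: Dict[str, str] = field(default_factory=dict)

    IUPAC = set("ACGTRYSWKMBDHVN")

    def __post_init__(self) -> None:
        for tf, ivs in self.peaks.items():
            for chrom, s, e in ivs:
                if s < 0 or s >= e:
                    raise ValueError(f"bad interval for {tf}: {chrom}:{s}-{e}")
            self.peaks[tf] = merge_intervals(ivs)
        for tf, motif in self.motifs.items():
            bad = set(motif.upper()) - self.IUPAC
            if bad:
                raise ValueError(f"non-IUPAC letters {bad} in motif for {tf}")

    @property
    def tfs(self) -> List[str]:
        return sorted(set(self.peaks) | set(self.motifs))


def merge_intervals(intervals: Sequence[Interval]) -> List[Interval]:
    """Union of possibly-overlapping intervals, per chromosome."""
    out: List[Interval] = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic study, for parameter-recovery tests."""

    true_tf_eqtls: Set[Tuple[str, str, str]]  # (tf, gene, variant)
    planted_afc_curve: Dict[Tuple[str, str, str], Dict[float, float]]
    confounds: List[Tuple[str, Dict[str, Tuple[float, float]]]]
    seed: int
    models: Dict[Tuple[str, str, str], OccupancyModel] = field(default_factory=dict)

    @property
    def true_pairs(self) -> Set[Tuple[str, str]]:
        return {(tf, gene) for tf, gene, _ in self.true_tf_eqtls}

    @property
    def true_genes(self) -> Set[str]:
        return {gene for _, gene, _ in self.true_tf_eqtls}


GenomeFetcher = Callable[[str, int, int], str]
"""Sequence accessor: (chrom, start, end) 0-based half-open -> uppercase bases."""


@dataclass
class SyntheticStudy:
    """All components of one simulated multi-tissue eQTL cohort."""

    genotypes: GenotypeMatrix
    tissues: List[TissueExpression]
    tf_ids: List[str]
    protein_medians: pd.DataFrame  # TFs x tissues
    annotations: AnnotationSet
    credible_sets: pd.DataFrame  # variant, gene, tissue
    asb_table: pd.DataFrame  # variant, tf, asb
    regulons: Dict[str, Dict[str, Set[str]]]  # type -> tf -> genes
    gxe_genes: Set[str]
    coloc_table: pd.DataFrame  # gene, tissue, trait, rcp, lead_variant
    allelic_counts: pd.DataFrame  # gene, variant, condition, ref/alt/other counts
    genome: Dict[str, str]
    truth: SimulationTruth
    gene_tss: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    xcell_scores: Dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def tissue_names(self) -> List[str]:
        return [t.tissue for t in self.tissues]

    def tissue(self, name: str) -> TissueExpression:
        for t in self.tissues:
            if t.tissue == name:
                return t
        raise KeyError(name)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Genome accessor (0-based half-open), truncated at contig edges."""
        seq = self.genome[chrom]
        return seq[max(0, start):min(len(seq), end)]
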