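"""Readers and writers for the study's on-disk formats.

A study directory holds the standard plain-text formats of the field:
VCF v4.2 genotypes, per-tissue expression/covariate/cell-type TSVs, BED
peak files, a motif consensus table, credible-set and ASB TSVs, GMT
regulons, a colocalization table, allelic knockdown counts, a FASTA genome
and a ground-truth table.  ``write_study``/``load_study`` round-trip a
:class:`~tfeqtl.types.SyntheticStudy` through this layout (planted aFC
curves and occupancy models are in-memory only and are not serialized).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Set

import numpy as np
import pandas as pd

from .types import (
    AnnotationSet,
    GenotypeMatrix,
    SimulationTruth,
    SyntheticStudy,
    TissueExpression,
)

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(geno: GenotypeMatrix, path: Path) -> None:
    """Biallelic SNVs with GT fields, VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = geno.variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.individuals) + "\n")
        for j, (vid, row) in enumerate(geno.variants.iterrows()):
            gts = [
                "./." if np.isnan(d) else _GT[int(d)] for d in geno.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: Path) -> GenotypeMatrix:
    """Load a plain VCF into a dosage matrix (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, cols, ids = [], [], []
    for v in vcf:
        gts = np.array(v.genotypes, dtype=float)[:, :2]
        gts[gts < 0] = np.nan
        cols.append(gts.sum(axis=1))
        ids.append(v.ID)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"], index=ids)
    dosages = np.column_stack(cols) if cols else np.empty((len(individuals), 0))
    with np.errstate(invalid="ignore"):
        af = np.nanmean(dosages, axis=0) / 2.0
    variants["maf"] = np.minimum(af, 1 - af)
    return GenotypeMatrix(dosages=dosages, individuals=individuals, variants=variants)


def write_fasta(genome: Dict[str, str], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: Path) -> Dict[str, str]:
    genome: Dict[str, str] = {}
    name, parts = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(parts)
                name, parts = line[1:].split()[0], []
            elif line:
                parts.append(line)
    if name is not None:
        genome[name] = "".join(parts)
    return genome


def write_gmt(regulons: Dict[str, Dict[str, Set[str]]], path: Path) -> None:
    """One GMT line per (TF, regulon type): '<tf>|<type>  <desc>  genes...'."""
    with open(path, "w") as fh:
        for rtype in sorted(regulons):
            for tf in sorted(regulons[rtype]):
                genes = sorted(regulons[rtype][tf])
                fh.write("\t".join([f"{tf}|{rtype}", rtype] + genes) + "\n")


def read_gmt(path: Path) -> Dict[str, Dict[str, Set[str]]]:
    out: Dict[str, Dict[str, Set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or "|" not in fields[0]:
                continue
            tf, rtype = fields[0].split("|", 1)
            out.setdefault(rtype, {})[tf] = set(fields[2:])
    return out


def write_bed(annotations: AnnotationSet, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    for tf, intervals in annotations.peaks.items():
        with open(directory / f"{tf}.bed", "w") as fh:
            for chrom, s, e in intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{tf}\n")


def read_bed_dir(directory: Path) -> Dict[str, list]:
    peaks = {}
    for bed in sorted(Path(directory).glob("*.bed")):
        tf = bed.stem
        ivs = []
        with open(bed) as fh:
            for line in fh:
                chrom, s, e = line.split("\t")[:3]
                ivs.append((chrom, int(s), int(e)))
        peaks[tf] = ivs
    return peaks


def write_study(study: SyntheticStudy, outdir: Path | str) -> Path:
    """Serialize a study to a directory of plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(study.genotypes, out / "genotypes.vcf")
    write_fasta(study.genome, out / "genome.fa")
    tdir = out / "tissues"
    tdir.mkdir(exist_ok=True)
    for tis in study.tissues:
        tis.tpm.rename_axis("gene_id").to_csv(tdir / f"{tis.tissue}.expression.tsv", sep="\t")
        tis.covariates.rename_axis("sample_id").to_csv(tdir / f"{tis.tissue}.covariates.tsv", sep="\t")
        if tis.tissue in study.xcell_scores:
            study.xcell_scores[tis.tissue].rename_axis("sample_id").to_csv(
                tdir / f"{tis.tissue}.xcell.tsv", sep="\t"
            )
    write_bed(study.annotations, out / "peaks")
    pd.DataFrame(
        sorted(study.annotations.motifs.items()), columns=["tf", "consensus"]
    ).to_csv(out / "motifs.tsv", sep="\t", index=False)
    study.credible_sets.to_csv(out / "credible_sets.tsv", sep="\t", index=False)
    study.asb_table.to_csv(out / "asb.tsv", sep="\t", index=False)
    write_gmt(study.regulons, out / "regulons.gmt")
    pd.Series(sorted(study.gxe_genes), name="gene").to_csv(out / "gxe_genes.tsv", sep="\t", index=False)
    study.coloc_table.to_csv(out / "coloc.tsv", sep="\t", index=False)
    study.allelic_counts.to_csv(out / "allelic_counts.tsv", sep="\t", index=False)
    study.protein_medians.rename_axis("tf").to_csv(out / "protein_medians.tsv", sep="\t")
    study.gene_tss.rename_axis("gene").rename("tss").to_csv(out / "genes.tsv", sep="\t")
    pd.DataFrame(
        sorted(study.truth.true_tf_eqtls), columns=["tf", "gene", "variant"]
    ).to_csv(out / "truth_tf_eqtls.tsv", sep="\t", index=False)
    (out / "meta.json").write_text(
        json.dumps({"tf_ids": study.tf_ids, "seed": study.truth.seed}, indent=2)
    )
    return out


def load_study(directory: Path | str) -> SyntheticStudy:
    """Load a study directory written by :func:`write_study`.

    The returned truth carries the planted (TF, gene, variant) triples only;
    occupancy models and aFC curves are not serialized.
    """
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    geno = read_vcf(d / "genotypes.vcf")
    genome = read_fasta(d / "genome.fa")
    tissues = []
    xcell = {}
    for expr_file in sorted((d / "tissues").glob("*.expression.tsv")):
        name = expr_file.name.replace(".expression.tsv", "")
        tpm = pd.read_csv(expr_file, sep="\t", index_col=0).rename_axis(None)
        cov_file = d / "tissues" / f"{name}.covariates.tsv"
        covs = (
            pd.read_csv(cov_file, sep="\t", index_col=0).rename_axis(None)
            if cov_file.exists() else pd.DataFrame()
        )
        tissues.append(TissueExpression(tissue=name, tpm=tpm, covariates=covs))
        xcell_file = d / "tissues" / f"{name}.xcell.tsv"
        if xcell_file.exists():
            xcell[name] = pd.read_csv(xcell_file, sep="\t", index_col=0).rename_axis(None)
    motifs = pd.read_csv(d / "motifs.tsv", sep="\t").set_index("tf")["consensus"].to_dict()
    annotations = AnnotationSet(peaks=read_bed_dir(d / "peaks"), motifs=motifs)
    truth_tab = pd.read_csv(d / "truth_tf_eqtls.tsv", sep="\t")
    truth = SimulationTruth(
        true_tf_eqtls={tuple(r) for r in truth_tab.itertuples(index=False)},
        planted_afc_curve={}, confounds=[], seed=int(meta["seed"]),
    )
    return SyntheticStudy(
        genotypes=geno,
        tissues=tissues,
        tf_ids=list(meta["tf_ids"]),
        protein_medians=pd.read_csv(d / "protein_medians.tsv", sep="\t", index_col=0).rename_axis(None),
        annotations=annotations,
        credible_sets=pd.read_csv(d / "credible_sets.tsv", sep="\t"),
        asb_table=pd.read_csv(d / "asb.tsv", sep="\t"),
        regulons=read_gmt(d / "regulons.gmt"),
        gxe_genes=set(pd.read_csv(d / "gxe_genes.tsv", sep="\t")["gene"]),
        coloc_table=pd.read_csv(d / "coloc.tsv", sep="\t"),
        allelic_counts=pd.read_csv(d / "allelic_counts.tsv", sep="\t"),
        genome=genome,
        truth=truth,
        gene_tss=pd.read_csv(d / "genes.tsv", sep="\t", index_col=0)["tss"],
        xcell_scores=xcell,
    )
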