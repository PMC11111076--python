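"""Dataset serialization: VCF genotypes, TSV covariates, PNG images.

The on-disk layout written by :func:`write_dataset` is::

    out_dir/
      genotypes.vcf        VCF 4.2, GT-only, one record per SNP
      covariates.tsv       id, age, sex, pigment, vessel, dr_grade
      images/{id}_{eye}.png
      manifest.tsv         subject_id, eye, image_path

Reading goes through cyvcf2, the standard variant reader, so the
round trip also validates that the emitted VCF is well-formed.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import FundusImage, GenotypePanel, SubjectRecord

__all__ = ["write_dataset", "read_genotypes_vcf", "read_dataset", "write_vcf"]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as minimal VCF 4.2 with GT fields only."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(panel.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        cols = "\t".join(panel.subject_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j in range(panel.n_snps):
            gts = "\t".join(_GT[int(g)] for g in panel.dosages[:, j])
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.snp_ids[j]}\t"
                f"{panel.ref[j]}\t{panel.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path) -> GenotypePanel:
    """Read a GT-only VCF back into a :class:`GenotypePanel`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = np.array(vcf.samples)
    chrom, pos, ref, alt, snp_ids, rows = [], [], [], [], [], []
    for rec in vcf:
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0] if rec.ALT else ".")
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        # gt_types: 0=hom-ref 1=het 3=hom-alt (2 = unknown)
        gt = rec.gt_types
        dos = np.where(gt == 3, 2, np.where(gt == 2, -1, gt))
        rows.append(dos)
    dosages = np.array(rows, dtype=np.int8).T
    p = dosages.mean(axis=0) / 2.0
    return GenotypePanel(
        dosages=dosages,
        chrom=np.array(chrom), pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref), alt=np.array(alt),
        maf=np.minimum(p, 1 - p),
        snp_ids=np.array(snp_ids), subject_ids=subject_ids,
    )


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.id, s.age, s.sex, s.pigment, s.vessel, s.dr_grade) for s in subjects],
        columns=["id", "age", "sex", "pigment", "vessel", "dr_grade"],
    )


def write_dataset(panel: GenotypePanel, subjects: list[SubjectRecord],
                  images: list[FundusImage], out_dir) -> pd.DataFrame:
    """Write the full dataset; returns the manifest (one row per image)."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)

    ids = {s.id for s in subjects}
    for img in images:
        if img.subject_id not in ids:
            raise ValueError(f"image subject {img.subject_id!r} not in subjects")

    write_vcf(panel, out / "genotypes.vcf")
    subjects_to_frame(subjects).to_csv(out / "covariates.tsv", sep="\t", index=False)

    rows = []
    for img in images:
        rel = f"images/{img.subject_id}_{img.eye}.png"
        Image.fromarray(img.pixels).save(out / rel)
        rows.append((img.subject_id, img.eye, rel))
    manifest = pd.DataFrame(rows, columns=["subject_id", "eye", "image_path"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_dataset(out_dir) -> tuple[GenotypePanel, pd.DataFrame, list[FundusImage]]:
    """Read back a dataset written by :func:`write_dataset`."""
    out = Path(out_dir)
    panel = read_genotypes_vcf(out / "genotypes.vcf")
    covars = pd.read_csv(out / "covariates.tsv", sep="\t")
    manifest = pd.read_csv(out / "manifest.tsv", sep="\t")
    images = []
    for _, row in manifest.iterrows():
        path = out / row.image_path
        if not path.exists():
            raise FileNotFoundError(
                f"missing image for subject {row.subject_id} eye {row.eye}: {path}"
            )
        images.append(FundusImage(
            pixels=np.asarray(Image.open(path).convert("RGB")),
            subject_id=str(row.subject_id), eye=str(row.eye),
        ))
    return panel, covars, images
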