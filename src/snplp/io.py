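"""Readers and writers for genotype + phenotype files.

Supported formats: a simple TSV genotype matrix (samples x SNPs) with a
two-column phenotype file, VCF 4.x (GT field, biallelic sites), and
PLINK-style additive-coded ``.raw`` tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import CASE, CONTROL, MISSING, UNKNOWN, GenotypeDataset

logger = logging.getLogger(__name__)

_PHENO_TOKENS = {
    "1": CASE,
    "0": CONTROL,
    "case": CASE,
    "control": CONTROL,
    "na": UNKNOWN,
    "unknown": UNKNOWN,
}


def read_phenotypes(path: str | Path) -> dict[str, int]:
    """Read a two-column (sample id, status) phenotype file.

    Status tokens: ``1``/``case`` for cases, ``0``/``control`` for
    controls, ``NA``/``unknown`` for unknown.  A header line is detected
    and skipped if its second token is not a recognised status.
    """
    phenos: dict[str, int] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        sid, tok = parts
        key = tok.strip().lower()
        if key not in _PHENO_TOKENS:
            if lineno == 1:  # header row
                continue
            raise ValueError(f"{path}:{lineno}: unknown phenotype token {tok!r}")
        if sid in phenos:
            raise ValueError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        phenos[sid] = _PHENO_TOKENS[key]
    return phenos


def read_tsv(genotype_path: str | Path, phenotype_path: str | Path) -> GenotypeDataset:
    """Read a delimited genotype matrix plus a phenotype file.

    The genotype file has a header row of SNP ids, a first column of
    sample ids, and cells in {0, 1, 2, NA}.
    """
    df = pd.read_csv(genotype_path, sep="\t", index_col=0, dtype=str)
    snp_ids = [str(c) for c in df.columns]
    sample_ids = [str(i) for i in df.index]
    geno = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            tok = str(values[i, j]).strip()
            if tok.lower() in ("na", "nan", "."):
                geno[i, j] = MISSING
            elif tok in ("0", "1", "2"):
                geno[i, j] = int(tok)
            else:
                raise ValueError(
                    f"{genotype_path}: invalid genotype {tok!r} at sample "
                    f"{sample_ids[i]!r}, SNP {snp_ids[j]!r}"
                )
    phenos = read_phenotypes(phenotype_path)
    unknown_ids = set(phenos) - set(sample_ids)
    if unknown_ids:
        raise ValueError(
            f"{phenotype_path}: sample ids not in genotype file: "
            f"{sorted(unknown_ids)[:5]}"
        )
    phenotypes = np.array([phenos.get(s, UNKNOWN) for s in sample_ids], dtype=np.int8)
    return GenotypeDataset(sample_ids, snp_ids, geno, phenotypes)


def write_tsv(
    dataset: GenotypeDataset,
    genotype_path: str | Path,
    phenotype_path: str | Path | None = None,
) -> None:
    """Write a dataset in the TSV dialect read by :func:`read_tsv`."""
    tokens = np.where(
        dataset.genotypes == MISSING, "NA", dataset.genotypes.astype(str)
    )
    df = pd.DataFrame(tokens, index=dataset.sample_ids, columns=dataset.snp_ids)
    df.to_csv(genotype_path, sep="\t", index_label="sample_id")
    if phenotype_path is not None:
        rev = {CASE: "1", CONTROL: "0", UNKNOWN: "NA"}
        with open(phenotype_path, "w") as fh:
            fh.write("sample_id\tstatus\n")
            for sid, ph in zip(dataset.sample_ids, dataset.phenotypes):
                fh.write(f"{sid}\t{rev[int(ph)]}\n")


def read_vcf(vcf_path: str | Path, phenotype_path: str | Path) -> GenotypeDataset:
    """Read genotypes from a VCF (GT field), counting the ALT allele.

    Multi-allelic records are skipped with a logged warning; ``./.``
    becomes missing.  ``snp_meta`` is filled from CHROM/POS/ID.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    sample_ids = [str(s) for s in vcf.samples]
    phenos = read_phenotypes(phenotype_path)
    if not set(phenos) & set(sample_ids):
        raise ValueError(
            f"no overlapping samples between {vcf_path} and {phenotype_path}"
        )
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    meta_rows: list[tuple[str, int]] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        # gts012=True: gt_types is 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        col = np.asarray(var.gt_types, dtype=np.int8)
        col[col == 3] = MISSING
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snp_ids.append(str(snp_id))
        columns.append(col)
        meta_rows.append((str(var.CHROM), int(var.POS)))
    if n_skipped:
        logger.warning("skipped %d multi-allelic records in %s", n_skipped, vcf_path)
    if not snp_ids:
        raise ValueError(f"{vcf_path}: no usable biallelic records")
    geno = np.column_stack(columns)
    phenotypes = np.array([phenos.get(s, UNKNOWN) for s in sample_ids], dtype=np.int8)
    meta = pd.DataFrame(meta_rows, columns=["chrom", "pos"])
    return GenotypeDataset(sample_ids, snp_ids, geno, phenotypes, snp_meta=meta)


def read_plink_raw(raw_path: str | Path) -> GenotypeDataset:
    """Read a PLINK additive-coded ``.raw`` export.

    Expects header columns FID IID PAT MAT SEX PHENOTYPE followed by one
    column per SNP; PHENOTYPE coded 2=case, 1=control, -9/0=unknown.
    """
    df = pd.read_csv(raw_path, sep=r"\s+", dtype=str)
    required = ["FID", "IID", "PHENOTYPE"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{raw_path}: missing header columns {missing_cols}")
    meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    snp_cols = [c for c in df.columns if c not in meta_cols]
    if not snp_cols:
        raise ValueError(f"{raw_path}: no genotype columns found")
    sample_ids = [str(i) for i in df["IID"]]

    pheno_map = {"2": CASE, "1": CONTROL, "-9": UNKNOWN, "0": UNKNOWN}
    phenotypes = np.empty(len(df), dtype=np.int8)
    for i, tok in enumerate(df["PHENOTYPE"]):
        key = str(tok).strip()
        key = key[:-2] if key.endswith(".0") else key
        if key not in pheno_map:
            raise ValueError(f"{raw_path}: invalid PHENOTYPE {tok!r} (row {i + 1})")
        phenotypes[i] = pheno_map[key]

    geno = np.empty((len(df), len(snp_cols)), dtype=np.int8)
    for j, col in enumerate(snp_cols):
        for i, tok in enumerate(df[col]):
            key = str(tok).strip()
            if key.lower() in ("na", "nan"):
                geno[i, j] = MISSING
            elif key in ("0", "1", "2") or key in ("0.0", "1.0", "2.0"):
                geno[i, j] = int(float(key))
            else:
                raise ValueError(
                    f"{raw_path}: non-numeric genotype {tok!r} at row {i + 1}, "
                    f"column {col!r}"
                )
    # PLINK suffixes the counted allele, e.g. rs123_A; strip it for SNP ids
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    if len(set(snp_ids)) != len(snp_ids):
        snp_ids = snp_cols
    return GenotypeDataset(sample_ids, snp_ids, geno, phenotypes)


def intersect_snps(
    a: GenotypeDataset, b: GenotypeDataset
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Restrict two datasets to their shared SNPs, in identical order.

    The shared SNPs keep dataset ``a``'s column order.  Raises if the
    intersection is empty.
    """
    shared = set(a.snp_ids) & set(b.snp_ids)
    if not shared:
        raise ValueError("no SNPs shared between the two datasets")
    order = [s for s in a.snp_ids if s in shared]
    return a.subset_snps(order), b.subset_snps(order)
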