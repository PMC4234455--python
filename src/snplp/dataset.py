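"""Canonical in-memory container for case/control genotype data.

Genotypes are stored as minor (ALT) allele counts in {0, 1, 2} with
``MISSING`` (-1) for no-calls, in a dense ``int8`` matrix of shape
(n_samples, n_snps).  Phenotypes are ``CASE`` (1), ``CONTROL`` (0) or
``UNKNOWN`` (-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1
CASE: int = 1
CONTROL: int = 0
UNKNOWN: int = -1

_VALID_GENOTYPES = frozenset({0, 1, 2, MISSING})


@dataclass
class GenotypeDataset:
    """Samples x SNPs genotype matrix plus case/control labels.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per matrix row.
    snp_ids : list of str
        Unique SNP identifiers, one per matrix column.
    genotypes : ndarray of int8, shape (n_samples, n_snps)
        Minor-allele counts, ``MISSING`` for no-calls.
    phenotypes : ndarray of int8, shape (n_samples,)
        ``CASE``, ``CONTROL`` or ``UNKNOWN`` per sample.
    snp_meta : DataFrame, optional
        Per-SNP metadata indexed like ``snp_ids`` with columns
        ``chrom`` and ``pos`` (1-based).
    """

    sample_ids: list[str]
    snp_ids: list[str]
    genotypes: np.ndarray
    phenotypes: np.ndarray
    snp_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.int8)
        self.sample_ids = list(map(str, self.sample_ids))
        self.snp_ids = list(map(str, self.snp_ids))
        self.validate()

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotypes == CASE

    @property
    def control_mask(self) -> np.ndarray:
        return self.phenotypes == CONTROL

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return int(self.control_mask.sum())

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids contain duplicates")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids contain duplicates")
        if self.genotypes.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.snp_ids)})"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype value {int(self.genotypes[i, j])} at sample "
                f"{self.sample_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )
        if self.phenotypes.shape != (len(self.sample_ids),):
            raise ValueError("phenotype vector length does not match sample count")
        bad_ph = ~np.isin(self.phenotypes, (CASE, CONTROL, UNKNOWN))
        if bad_ph.any():
            i = int(np.argwhere(bad_ph)[0][0])
            raise ValueError(
                f"invalid phenotype {int(self.phenotypes[i])} for sample "
                f"{self.sample_ids[i]!r}"
            )

    def require_cases_and_controls(self) -> None:
        """Raise unless the dataset contains at least one case and one control."""
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError(
                f"ranking requires both classes; found {self.n_cases} cases "
                f"and {self.n_controls} controls"
            )

    # -- subsetting ----------------------------------------------------------
    def subset_samples(self, index: np.ndarray) -> "GenotypeDataset":
        """Return a dataset restricted to the given sample row indices."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in index],
            snp_ids=list(self.snp_ids),
            genotypes=self.genotypes[index],
            phenotypes=self.phenotypes[index],
            snp_meta=self.snp_meta,
        )

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeDataset":
        """Return a dataset restricted to the given SNPs, in the given order."""
        pos = {s: j for j, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in pos]
        if missing:
            raise KeyError(f"SNPs not in dataset: {missing[:5]}")
        cols = np.array([pos[s] for s in snp_ids], dtype=int)
        meta = None
        if self.snp_meta is not None:
            meta = self.snp_meta.iloc[cols].reset_index(drop=True)
        return GenotypeDataset(
            sample_ids=list(self.sample_ids),
            snp_ids=list(snp_ids),
            genotypes=self.genotypes[:, cols],
            phenotypes=self.phenotypes,
            snp_meta=meta,
        )
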