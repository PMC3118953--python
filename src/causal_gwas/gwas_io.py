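"""Genotype dataset container and text-format I/O.

The in-memory representation is a subjects × SNPs matrix of minor-allele
dosages (0/1/2), with ``MISSING`` (-1) marking absent genotype calls.
Two text dialects are supported:

* ``ped-map`` — whitespace-delimited PLINK-style .ped/.map pair; genotypes
  are allele pairs, missing calls are ``0 0``, phenotype is coded 2=case /
  1=control.
* ``dosage-table`` — a TSV with a ``subject_id`` column, a ``phenotype``
  column (1=case, 0=control) and one column of 0/1/2 dosages per SNP;
  missing calls are ``NA`` or ``.``.

Coordinates are 1-based. Minor alleles are determined per dataset from the
pooled (cases + controls) allele counts; ties break to the lexicographically
smaller allele.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING: int = -1

PED_MAP = "ped-map"
DOSAGE_TABLE = "dosage-table"
_DOSAGE_MISSING_TOKENS = {"NA", ".", ""}


@dataclass(frozen=True)
class SNPInfo:
    """Metadata for one biallelic SNP (1-based coordinates)."""

    snp_id: str
    chromosome: str
    position: int
    allele_minor: str
    allele_major: str
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"SNP {self.snp_id}: position must be >= 1, got {self.position}"
            )


@dataclass
class GenotypeDataset:
    """Case-control genotype matrix with SNP metadata and phenotype.

    ``calls`` holds minor-allele dosages in {0, 1, 2} with ``MISSING`` for
    absent calls; rows are subjects, columns are SNPs in ``snps`` order.
    ``phenotype`` is 1 for cases, 0 for controls (optional, but required by
    all phenotype-aware stages). ``covariates`` may carry extra per-subject
    binary columns such as shared-epitope status.
    """

    calls: np.ndarray
    snps: list[SNPInfo]
    subject_ids: list[str]
    phenotype: Optional[np.ndarray] = None
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D subjects × SNPs matrix")
        n_subj, n_snp = self.calls.shape
        if n_subj != len(self.subject_ids):
            raise ValueError("row count does not match subject_ids")
        if n_snp != len(self.snps):
            raise ValueError("column count does not match snps")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_id values must be unique")
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = self.calls[~valid].flat[0]
            raise ValueError(f"invalid genotype call value {bad}")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
            if self.phenotype.shape != (n_subj,):
                raise ValueError("phenotype length does not match subjects")
            if not np.isin(self.phenotype, (0, 1)).all():
                raise ValueError("phenotype must be binary 0/1")
            if n_subj and (self.phenotype.min() == self.phenotype.max()):
                raise ValueError("phenotype must include >=1 case and >=1 control")

    # -- convenience accessors -------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not present in dataset") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.calls[:, self.snp_index(snp_id)]

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeDataset":
        idx = [self.snp_index(s) for s in snp_ids]
        return replace(
            self,
            calls=self.calls[:, idx].copy(),
            snps=[self.snps[i] for i in idx],
        )

    def subset_subjects(self, indices: Sequence[int]) -> "GenotypeDataset":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            calls=self.calls[idx].copy(),
            subject_ids=[self.subject_ids[i] for i in idx],
            phenotype=None if self.phenotype is None else self.phenotype[idx].copy(),
            covariates=None
            if self.covariates is None
            else self.covariates.iloc[idx].reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_dataset(path: str, format: str) -> GenotypeDataset:
    """Read a genotype dataset.

    ``path`` is the .ped path (with the .map alongside, same stem) for the
    ped-map dialect, or the TSV path for the dosage-table dialect.
    """
    if format == PED_MAP:
        return _read_ped_map(path)
    if format == DOSAGE_TABLE:
        return _read_dosage(path)
    raise ValueError(f"unknown format {format!r}")


def _map_path(ped_path: str) -> str:
    stem, _ = os.path.splitext(ped_path)
    return stem + ".map"


def _read_ped_map(ped_path: str) -> GenotypeDataset:
    map_path = _map_path(ped_path)
    snps_meta: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{map_path}: malformed line {lineno}")
            chrom, snp_id, _gdist, pos = parts[:4]
            snps_meta.append((snp_id, chrom, int(pos)))
    n_snps = len(snps_meta)

    subject_ids: list[str] = []
    phenotypes: list[int] = []
    rows: list[list[tuple[str, str]]] = []
    any_pheno = False
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}: malformed line {lineno}: expected "
                    f"{6 + 2 * n_snps} fields, got {len(parts)}"
                )
            _fid, iid, _pat, _mat, _sex, pheno = parts[:6]
            subject_ids.append(iid)
            if pheno == "2":
                phenotypes.append(1)
                any_pheno = True
            elif pheno == "1":
                phenotypes.append(0)
                any_pheno = True
            else:
                phenotypes.append(MISSING)
            pairs = list(zip(parts[6::2], parts[7::2]))
            rows.append(pairs)

    calls = np.full((len(rows), n_snps), MISSING, dtype=np.int8)
    snps: list[SNPInfo] = []
    for j, (snp_id, chrom, pos) in enumerate(snps_meta):
        counts: Counter[str] = Counter()
        for pairs in rows:
            a, b = pairs[j]
            if a != "0" and b != "0":
                counts[a] += 1
                counts[b] += 1
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise ValueError(
                f"SNP {snp_id}: more than two alleles observed ({', '.join(alleles)})"
            )
        if len(alleles) == 0:
            minor, major = "A", "A"
        elif len(alleles) == 1:
            minor, major = alleles[0], alleles[0]
        else:
            a1, a2 = alleles  # lexicographic order
            if counts[a1] < counts[a2]:
                minor, major = a1, a2
            elif counts[a2] < counts[a1]:
                minor, major = a2, a1
            else:  # tie -> lexicographically smaller allele is minor
                minor, major = a1, a2
        snps.append(SNPInfo(snp_id, chrom, pos, minor, major))
        for i, pairs in enumerate(rows):
            a, b = pairs[j]
            if a == "0" or b == "0":
                continue
            calls[i, j] = (a == minor) + (b == minor)

    phen_arr: Optional[np.ndarray] = None
    if any_pheno and all(p in (0, 1) for p in phenotypes):
        phen_arr = np.asarray(phenotypes, dtype=np.int8)
    return GenotypeDataset(calls, snps, subject_ids, phen_arr)


def _read_dosage(path: str) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "subject_id" not in df.columns or "phenotype" not in df.columns:
        raise ValueError(f"{path}: dosage table needs subject_id and phenotype columns")
    snp_cols = [c for c in df.columns if c not in ("subject_id", "phenotype")]
    calls = np.full((len(df), len(snp_cols)), MISSING, dtype=np.int8)
    for j, col in enumerate(snp_cols):
        for i, tok in enumerate(df[col]):
            tok = tok.strip()
            if tok in _DOSAGE_MISSING_TOKENS:
                continue
            if tok not in ("0", "1", "2"):
                raise ValueError(f"{path}: malformed line {i + 2}: dosage {tok!r}")
            calls[i, j] = int(tok)
    # dosage tables carry no allele letters/coordinates; synthesize metadata
    snps = [SNPInfo(s, "0", j + 1, "A", "B") for j, s in enumerate(snp_cols)]
    phen_tokens = [t.strip() for t in df["phenotype"]]
    phen_arr: Optional[np.ndarray] = None
    if all(t in ("0", "1") for t in phen_tokens) and phen_tokens:
        phen_arr = np.asarray([int(t) for t in phen_tokens], dtype=np.int8)
    return GenotypeDataset(calls, snps, list(df["subject_id"]), phen_arr)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_dataset(ds: GenotypeDataset, path: str, format: str) -> list[str]:
    """Write ``ds``; returns the list of file paths produced.

    Output is deterministic for a fixed dataset (column order follows
    ``ds.snps``).
    """
    if format == PED_MAP:
        return _write_ped_map(ds, path)
    if format == DOSAGE_TABLE:
        return _write_dosage(ds, path)
    raise ValueError(f"unknown format {format!r}")


def _write_ped_map(ds: GenotypeDataset, ped_path: str) -> list[str]:
    map_path = _map_path(ped_path)
    with open(map_path, "w") as fh:
        for s in ds.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(ds.subject_ids):
            if ds.phenotype is None:
                pheno = "0"
            else:
                pheno = "2" if ds.phenotype[i] == 1 else "1"
            fields = [sid, sid, "0", "0", "0", pheno]
            for j, s in enumerate(ds.snps):
                d = ds.calls[i, j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [s.allele_major, s.allele_major]
                elif d == 1:
                    fields += [s.allele_minor, s.allele_major]
                else:
                    fields += [s.allele_minor, s.allele_minor]
            fh.write(" ".join(fields) + "\n")
    return [ped_path, map_path]


def _write_dosage(ds: GenotypeDataset, path: str) -> list[str]:
    with open(path, "w") as fh:
        fh.write("\t".join(["subject_id", "phenotype"] + ds.snp_ids) + "\n")
        for i, sid in enumerate(ds.subject_ids):
            pheno = "NA" if ds.phenotype is None else str(int(ds.phenotype[i]))
            toks = [
                "NA" if d == MISSING else str(int(d)) for d in ds.calls[i]
            ]
            fh.write("\t".join([sid, pheno] + toks) + "\n")
    return [path]
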