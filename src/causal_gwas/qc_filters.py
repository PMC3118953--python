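"""SNP quality-control filters: call rate, MAF, Hardy-Weinberg.

The three filters are applied sequentially in that order, and the report
counts each step's removals among the survivors of the previous step, so
``n_output = n_input − Σ removals`` always holds. Thresholds are strict:
call rate must exceed ``min_rate`` and MAF must exceed ``min_maf``. The
Hardy-Weinberg χ² test is computed in controls by default (configurable to
the pooled cohort), and a SNP is retained when its p-value is ≥ α.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gwas_io import MISSING, GenotypeDataset
from .stats_core import hwe_test, maf


@dataclass
class QCConfig:
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    hwe_alpha: float = 1e-5
    hwe_cohort: str = "controls"  # or "all"


@dataclass
class QCReport:
    n_input: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    n_output: int
    reasons: dict[str, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_call_rate": self.removed_call_rate,
            "removed_maf": self.removed_maf,
            "removed_hwe": self.removed_hwe,
            "n_output": self.n_output,
            "reasons": self.reasons,
        }


def _keep(ds: GenotypeDataset, keep_mask: np.ndarray) -> tuple[GenotypeDataset, set[str]]:
    ids = np.asarray(ds.snp_ids)
    removed = set(ids[~keep_mask])
    return ds.subset_snps(list(ids[keep_mask])), removed


def call_rate_filter(
    ds: GenotypeDataset, min_rate: float = 0.95
) -> tuple[GenotypeDataset, set[str]]:
    """Retain SNPs called in strictly more than ``min_rate`` of subjects."""
    if not (0.0 < min_rate <= 1.0):
        raise ValueError("min_rate must lie in (0, 1]")
    present = (ds.calls != MISSING).mean(axis=0) if ds.n_subjects else np.ones(ds.n_snps)
    return _keep(ds, present > min_rate)


def maf_filter(
    ds: GenotypeDataset, min_maf: float = 0.01
) -> tuple[GenotypeDataset, set[str]]:
    """Retain SNPs with pooled minor-allele frequency strictly above ``min_maf``."""
    if not (0.0 <= min_maf < 0.5):
        raise ValueError("min_maf must lie in [0, 0.5)")
    keep = np.zeros(ds.n_snps, dtype=bool)
    for j in range(ds.n_snps):
        col = ds.calls[:, j]
        if (col == MISSING).all():
            keep[j] = False  # no data
        else:
            keep[j] = maf(col) > min_maf
    return _keep(ds, keep)


def hwe_filter(
    ds: GenotypeDataset, alpha: float = 1e-5, cohort: str = "controls"
) -> tuple[GenotypeDataset, set[str]]:
    """Retain SNPs whose Hardy-Weinberg χ² p-value is ≥ ``alpha``.

    ``cohort='controls'`` tests in phenotype-0 subjects (requires a
    phenotype); ``cohort='all'`` pools everyone.
    """
    if cohort == "controls":
        if ds.phenotype is None:
            raise ValueError("cohort='controls' requires a phenotype")
        calls = ds.calls[ds.phenotype == 0]
    elif cohort == "all":
        calls = ds.calls
    else:
        raise ValueError(f"unknown cohort {cohort!r}")
    keep = np.ones(ds.n_snps, dtype=bool)
    for j in range(ds.n_snps):
        col = calls[:, j]
        col = col[col != MISSING]
        if len(col) == 0:
            continue  # no information: retain
        p = hwe_test(int(np.sum(col == 2)), int(np.sum(col == 1)), int(np.sum(col == 0)))
        keep[j] = p >= alpha
    return _keep(ds, keep)


def apply_qc(
    ds: GenotypeDataset, config: QCConfig | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Call rate → MAF → HWE, with per-step removal bookkeeping."""
    cfg = config or QCConfig()
    n_input = ds.n_snps
    reasons: dict[str, str] = {}

    ds1, rm_cr = call_rate_filter(ds, cfg.min_call_rate)
    reasons.update({s: "call_rate" for s in rm_cr})
    ds2, rm_maf = maf_filter(ds1, cfg.min_maf)
    for s in rm_maf:
        col = ds1.column(s)
        reasons[s] = "no data" if (col == MISSING).all() else "maf"
    ds3, rm_hwe = hwe_filter(ds2, cfg.hwe_alpha, cfg.hwe_cohort)
    reasons.update({s: "hwe" for s in rm_hwe})

    report = QCReport(
        n_input=n_input,
        removed_call_rate=len(rm_cr),
        removed_maf=len(rm_maf),
        removed_hwe=len(rm_hwe),
        n_output=ds3.n_snps,
        reasons=reasons,
    )
    assert report.n_output == n_input - (
        report.removed_call_rate + report.removed_maf + report.removed_hwe
    )
    return ds3, report
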