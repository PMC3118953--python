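"""Data audits: phenotype-linked missingness patterns and conditional-
independence auditing of externally reported marker SNPs.

*Missingness audit* — every genotype call is binarized (1 = missing), each
SNP's missingness indicator is G²-tested against the phenotype, the
significant set is controlled at a BH false-discovery rate, significant
missingness is tested for hypergeometric enrichment inside a coordinate
window (e.g. an MHC-like locus), and a kernel-ridge classifier trained on
the binarized matrix over a stratified hold-out quantifies how predictive
the missingness pattern alone is of case status. Under purely random
missingness the classifier sits at AUC ≈ 0.5; phenotype-dependent
missingness drives it far above.

*Conditional-independence audit* — for each externally supplied known
marker SNP, find the smallest subset of a discovered Markov boundary that
renders it statistically independent of the phenotype (reliable G² at α),
searching subsets in increasing size. A marker needing no subset was never
marginally associated; a marker with no such subset carries information the
boundary does not subsume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .causal_discovery import DiscoveryConfig, MarkovBoundary
from .evaluation import ROCReport, roc_report, stratified_split
from .gwas_io import MISSING, GenotypeDataset
from .prediction import krr_fit, krr_predict, tune_krr
from .stats_core import bh_fdr, g2_test, hypergeom_enrichment


@dataclass
class MissingnessReport:
    n_snps_with_missing: int
    n_significant: int
    locus: tuple[str, int, int]
    n_locus_missing: int
    n_locus_significant: int
    enrichment_p: Optional[float]
    classifier: Optional[ROCReport]
    significant_snp_ids: list[str]

    def to_json_dict(self) -> dict:
        return {
            "n_snps_with_missing": self.n_snps_with_missing,
            "n_significant": self.n_significant,
            "locus": list(self.locus),
            "n_locus_missing": self.n_locus_missing,
            "n_locus_significant": self.n_locus_significant,
            "enrichment_p": self.enrichment_p,
            "classifier": None if self.classifier is None else self.classifier.to_json_dict(),
            "significant_snp_ids": self.significant_snp_ids,
        }


@dataclass
class CIAuditRow:
    snp_id: str
    marginally_associated: Optional[bool]
    minimal_conditioning_set: Optional[list[str]]
    minimal_set_size: int
    note: str = ""

    def to_json_dict(self) -> dict:
        return {
            "snp_id": self.snp_id,
            "marginally_associated": self.marginally_associated,
            "minimal_conditioning_set": self.minimal_conditioning_set,
            "minimal_set_size": self.minimal_set_size,
            "note": self.note,
        }


def binarize_missing(ds: GenotypeDataset) -> np.ndarray:
    """Subjects × SNPs matrix with 1 where the call is missing, else 0."""
    return (ds.calls == MISSING).astype(np.uint8)


def missingness_analysis(
    ds: GenotypeDataset,
    locus: tuple[str, int, int],
    fdr_q: float = 0.05,
    seed: int = 0,
    alpha: float = 0.05,
    min_avg_cell: int = 5,
    classifier: bool = True,
    lambda_grid: Optional[Sequence[float]] = None,
    gamma_grid: Optional[Sequence[float]] = None,
    cv_folds: int = 10,
) -> MissingnessReport:
    """Phenotype-association and locus-enrichment audit of missing calls."""
    if ds.phenotype is None:
        raise ValueError("missingness analysis requires a phenotype")
    m = binarize_missing(ds)
    with_missing = np.flatnonzero(m.sum(axis=0) > 0)
    ids = np.asarray(ds.snp_ids)

    p_values = np.array(
        [
            g2_test(ds.phenotype, m[:, j], alpha=alpha, min_avg_cell=min_avg_cell).p_value
            for j in with_missing
        ]
    )
    sig_mask = bh_fdr(p_values, fdr_q) if len(p_values) else np.zeros(0, dtype=bool)
    sig_ids = set(ids[with_missing[sig_mask]])

    chrom, start, end = locus
    in_locus = np.array(
        [s.chromosome == chrom and start <= s.position <= end for s in ds.snps]
    )
    locus_missing = [j for j in with_missing if in_locus[j]]
    locus_sig = [j for j in locus_missing if ids[j] in sig_ids]

    enrichment_p: Optional[float] = None
    if locus_missing:
        enrichment_p = hypergeom_enrichment(
            N=len(with_missing),
            K=int(sig_mask.sum()),
            n=len(locus_missing),
            k=len(locus_sig),
        )

    roc: Optional[ROCReport] = None
    if classifier and len(with_missing):
        train, test = stratified_split(ds, seed=seed)
        Xtr = binarize_missing(train)[:, with_missing].astype(float)
        Xte = binarize_missing(test)[:, with_missing].astype(float)
        gam_grid = (
            gamma_grid
            if gamma_grid is not None
            else 2.0 ** np.arange(-3, 4) / len(with_missing)
        )
        lam, gamma, _ = tune_krr(
            Xtr, train.phenotype, lambda_grid, gam_grid, folds=cv_folds, seed=seed
        )
        model = krr_fit(Xtr, train.phenotype.astype(float), lam, gamma)
        roc = roc_report(krr_predict(model, Xte), test.phenotype)

    return MissingnessReport(
        n_snps_with_missing=len(with_missing),
        n_significant=int(sig_mask.sum()),
        locus=locus,
        n_locus_missing=len(locus_missing),
        n_locus_significant=len(locus_sig),
        enrichment_p=enrichment_p,
        classifier=roc,
        significant_snp_ids=sorted(sig_ids),
    )


def ci_audit(
    ds: GenotypeDataset,
    known_snps: Sequence[str],
    boundary: MarkovBoundary | Sequence[str],
    alpha: float = 0.05,
    max_subset: int = 4,
    min_avg_cell: int = 5,
) -> list[CIAuditRow]:
    """Minimal boundary subsets rendering each known marker independent.

    Absent markers and markers inside the boundary itself are reported with
    a note, not errored.
    """
    import itertools

    if ds.phenotype is None:
        raise ValueError("CI audit requires a phenotype")
    b_ids = sorted(
        boundary.snp_ids if isinstance(boundary, MarkovBoundary) else boundary
    )
    present = set(ds.snp_ids)
    rows: list[CIAuditRow] = []
    for snp in known_snps:
        if snp not in present:
            rows.append(
                CIAuditRow(snp, None, None, 0, note="not genotyped in dataset")
            )
            continue
        if snp in b_ids:
            rows.append(
                CIAuditRow(snp, True, None, 0, note="member of the discovered boundary")
            )
            continue
        x = ds.column(snp)
        marg = g2_test(ds.phenotype, x, alpha=alpha, min_avg_cell=min_avg_cell)
        if not (marg.reliable and marg.independent is False):
            rows.append(CIAuditRow(snp, False, [], 0))
            continue
        found: Optional[list[str]] = None
        for k in range(1, min(max_subset, len(b_ids)) + 1):
            for combo in itertools.combinations(b_ids, k):
                res = g2_test(
                    ds.phenotype,
                    x,
                    [ds.column(z) for z in combo],
                    alpha=alpha,
                    min_avg_cell=min_avg_cell,
                )
                if res.reliable and res.independent:
                    found = list(combo)
                    break
            if found is not None:
                break
        if found is None:
            rows.append(
                CIAuditRow(snp, True, None, -1, note="no conditioning set found")
            )
        else:
            rows.append(CIAuditRow(snp, True, found, len(found)))
    return rows
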