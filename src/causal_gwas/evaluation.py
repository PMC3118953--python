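"""Hold-out evaluation: stratified splits, AUC, DeLong confidence intervals,
and the multi-split robustness protocol.

AUC is the Mann-Whitney statistic (ties counted ½). The DeLong interval is
AUC ± z·√(S₁₀/m + S₀₁/n), with S₁₀/S₀₁ the sample variances of the case and
control placement values, truncated to [0, 1].

The robustness protocol repeats, over many random stratified splits:
Markov-boundary discovery on the training part, kernel-ridge fitting per
boundary, and AUC on the held-out part; it aggregates the AUC distribution
and each SNP's selection frequency (membership in any boundary of the
split). A planted causal SNP should be selected in well over half the
splits; an incidental one should not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve

from .causal_discovery import DiscoveryConfig, tie_star
from .gwas_io import GenotypeDataset
from .prediction import fit_signature, predict_signature


@dataclass
class ROCReport:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_cases: int
    n_controls: int

    def to_json_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "curve": {"fpr": list(map(float, self.fpr)), "tpr": list(map(float, self.tpr))},
        }


@dataclass
class RobustnessReport:
    split_aucs: list[float]
    auc_mean: float
    auc_sd: float
    selection_frequency: dict[str, float]
    failures: list[tuple[int, str]] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "split_aucs": self.split_aucs,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "selection_frequency": self.selection_frequency,
            "failures": self.failures,
        }


def stratified_split(
    ds: GenotypeDataset, train_fraction: float = 2 / 3, seed: int = 0
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Random split preserving the case:control proportion.

    Per stratum, the training count is round-half-up of fraction × stratum
    size; train and test partition the subjects.
    """
    if ds.phenotype is None:
        raise ValueError("stratified split requires a phenotype")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in (1, 0):
        stratum = np.flatnonzero(ds.phenotype == label)
        if len(stratum) == 0:
            raise ValueError(f"empty stratum for phenotype {label}")
        n_train = int(np.floor(train_fraction * len(stratum) + 0.5))
        perm = rng.permutation(len(stratum))
        train_idx.extend(stratum[perm[:n_train]])
        test_idx.extend(stratum[perm[n_train:]])
    return ds.subset_subjects(sorted(train_idx)), ds.subset_subjects(sorted(test_idx))


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney with ties counted ½)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    diff = cases[:, None] - controls[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), (1.0 - psi).mean(axis=0)


def delong_ci(
    scores: Sequence[float], labels: Sequence[int], level: float = 0.95
) -> tuple[float, float]:
    """DeLong confidence interval for the AUC, truncated to [0, 1]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    m, n = int(np.sum(y == 1)), int(np.sum(y == 0))
    if m < 2 or n < 2:
        raise ValueError("need at least 2 subjects per class")
    v10, v01 = _placements(s, y)
    a = float(v10.mean())
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    if var <= 0:
        return (a, a)
    z = float(norm.ppf((1 + level) / 2))
    half = z * np.sqrt(var)
    return (max(0.0, a - half), min(1.0, a + half))


def roc_report(
    scores: Sequence[float], labels: Sequence[int], level: float = 0.95
) -> ROCReport:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    fpr, tpr, _ = roc_curve(y, s)
    lo, hi = delong_ci(s, y, level)
    return ROCReport(
        auc=auc(s, y),
        ci_low=lo,
        ci_high=hi,
        fpr=fpr,
        tpr=tpr,
        n_cases=int(np.sum(y == 1)),
        n_controls=int(np.sum(y == 0)),
    )


def robustness(
    ds: GenotypeDataset,
    n_splits: int = 1000,
    discovery: Optional[DiscoveryConfig] = None,
    lambda_grid: Optional[Sequence[float]] = None,
    gamma_grid: Optional[Sequence[float]] = None,
    cv_folds: int = 10,
    train_fraction: float = 2 / 3,
    seed: int = 0,
) -> RobustnessReport:
    """Repeat split → discovery → fit → held-out AUC over many random splits."""
    cfg = discovery or DiscoveryConfig()
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_splits) % (2**31)
    split_aucs: list[float] = []
    counts = {s: 0 for s in ds.snp_ids}
    failures: list[tuple[int, str]] = []
    for i in range(n_splits):
        try:
            train, test = stratified_split(ds, train_fraction, int(child_seeds[2 * i]))
            tie = tie_star(train, cfg)
            selected = set().union(*(b.as_set() for b in tie.boundaries))
            for s in selected:
                counts[s] += 1
            aucs = []
            for b in tie.boundaries:
                if not b.snp_ids:
                    continue
                model = fit_signature(
                    train,
                    b.snp_ids,
                    lambda_grid,
                    gamma_grid,
                    folds=cv_folds,
                    seed=int(child_seeds[2 * i + 1]),
                )
                scores = predict_signature(model, test)
                aucs.append(auc(scores, test.phenotype))
            split_aucs.append(float(np.mean(aucs)) if aucs else 0.5)
        except Exception as exc:  # record, never silently drop
            failures.append((i, f"{type(exc).__name__}: {exc}"))
    freq = {s: counts[s] / n_splits for s in counts}
    return RobustnessReport(
        split_aucs=split_aucs,
        auc_mean=float(np.mean(split_aucs)) if split_aucs else float("nan"),
        auc_sd=float(np.std(split_aucs, ddof=1)) if len(split_aucs) > 1 else 0.0,
        selection_frequency=freq,
        failures=failures,
    )
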