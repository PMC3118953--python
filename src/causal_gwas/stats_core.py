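"""Discrete statistics shared by every stage of the pipeline.

The workhorse is the G² (likelihood-ratio) test of marginal or conditional
independence between discrete variables,

    G² = 2 · Σ_s Σ_{t,x} O ln(O / E),

summed over conditioning strata ``s``, with expectations ``E`` formed from
the product of the row/column margins within each stratum. Degrees of
freedom count, per non-empty stratum, only the target and variable levels
with non-zero stratum margins. A test is *reliable* when the sample affords
an average of at least ``min_avg_cell`` observations per contingency cell,
n ≥ min_avg_cell · L(target) · L(x) · Π L(cond) — the heuristic that also
yields the maximum conditioning-set size

    max-k = ⌊ log_c ( n / (min_avg_cell · L(target) · L(x)) ) ⌋.

An unreliable test renders no independence decision: callers must not
conclude independence from it.

Also provided: the 1-df χ² Hardy-Weinberg goodness-of-fit test, minor allele
frequency, genotype-dosage (composite) LD r², the upper-tail hypergeometric
enrichment test, and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .gwas_io import MISSING


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one G² (conditional) independence test.

    ``independent`` is the decision at the supplied α and is ``None`` when
    the test is unreliable (no decision).
    """

    statistic: float
    df: int
    p_value: float
    reliable: bool
    independent: Optional[bool]
    n: int


def _drop_missing(columns: Sequence[np.ndarray]) -> list[np.ndarray]:
    cols = [np.asarray(c) for c in columns]
    keep = np.ones(len(cols[0]), dtype=bool)
    for c in cols:
        if np.issubdtype(c.dtype, np.floating):
            keep &= ~np.isnan(c)
            keep &= c != MISSING
        else:
            keep &= c != MISSING
    return [c[keep] for c in cols]


def g2_test(
    target: np.ndarray,
    x: np.ndarray,
    cond: Sequence[np.ndarray] = (),
    alpha: float = 0.05,
    min_avg_cell: int = 5,
) -> CITestResult:
    """G² test of ``x ⊥ target | cond`` on discrete columns.

    Rows with a missing value (``MISSING`` or NaN) in any tested column are
    dropped pairwise for this test only.
    """
    cols = _drop_missing([target, x, *cond])
    y, xv, zs = cols[0], cols[1], cols[2:]
    n = len(y)

    y_levels, y_codes = np.unique(y, return_inverse=True)
    if len(y_levels) < 2:
        raise ValueError("degenerate target: fewer than two observed levels")
    x_levels, x_codes = np.unique(xv, return_inverse=True)
    ly, lx = len(y_levels), len(x_levels)

    n_strata = 1
    stratum = np.zeros(n, dtype=np.int64)
    cells = ly * lx
    for z in zs:
        z_levels, z_codes = np.unique(z, return_inverse=True)
        stratum = stratum * len(z_levels) + z_codes
        n_strata *= len(z_levels)
        cells *= len(z_levels)

    reliable = n >= min_avg_cell * cells

    joint = (stratum * ly + y_codes) * lx + x_codes
    counts = np.bincount(joint, minlength=n_strata * ly * lx).reshape(
        n_strata, ly, lx
    )

    g2 = 0.0
    df = 0
    for tab in counts:
        tot = tab.sum()
        if tot == 0:
            continue
        row = tab.sum(axis=1)
        col = tab.sum(axis=0)
        expected = np.outer(row, col) / tot
        mask = tab > 0
        g2 += 2.0 * float(np.sum(tab[mask] * np.log(tab[mask] / expected[mask])))
        df += max(int((row > 0).sum()) - 1, 0) * max(int((col > 0).sum()) - 1, 0)

    p = float(sps.chi2.sf(g2, df)) if df > 0 else 1.0
    independent: Optional[bool] = (p > alpha) if reliable else None
    return CITestResult(g2, df, p, reliable, independent, n)


def max_conditioning_size(
    n: int,
    min_avg_cell: int = 5,
    target_levels: int = 2,
    x_levels: int = 3,
    cond_levels: int = 3,
) -> int:
    """Largest conditioning-set size affording ``min_avg_cell`` per cell.

    ⌊ log_{cond_levels}( n / (min_avg_cell · target_levels · x_levels) ) ⌋,
    floored at 0.
    """
    if min(n, min_avg_cell, target_levels, x_levels, cond_levels) < 1:
        raise ValueError("all arguments must be >= 1")
    arg = n / (min_avg_cell * target_levels * x_levels)
    if arg < 1.0:
        return 0
    return int(math.floor(math.log(arg) / math.log(cond_levels) + 1e-12))


def hwe_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Hardy-Weinberg 1-df χ² goodness-of-fit p-value on genotype counts."""
    n = n_hom_minor + n_het + n_hom_major
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_hom_minor + n_het) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_hom_minor, n_het, n_hom_major], dtype=float)
    nz = expected > 0
    chi2 = float(np.sum((observed[nz] - expected[nz]) ** 2 / expected[nz]))
    return float(sps.chi2.sf(chi2, 1))


def hwe_statistic(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """The χ² statistic behind :func:`hwe_test` (1 df)."""
    n = n_hom_minor + n_het + n_hom_major
    p = (2 * n_hom_minor + n_het) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_hom_minor, n_het, n_hom_major], dtype=float)
    nz = expected > 0
    return float(np.sum((observed[nz] - expected[nz]) ** 2 / expected[nz]))


def maf(column: np.ndarray) -> float:
    """Minor-allele frequency of a dosage column (dataset orientation).

    (2·n_hom_minor + n_het) / (2·n_non_missing) on non-missing calls.
    """
    col = np.asarray(column)
    col = col[col != MISSING]
    if len(col) == 0:
        raise ValueError("all calls missing: MAF undefined")
    return float((2 * np.sum(col == 2) + np.sum(col == 1)) / (2 * len(col)))


def ld_r2(snp_a: np.ndarray, snp_b: np.ndarray) -> float:
    """Squared Pearson correlation of dosages (composite LD r²)."""
    a, b = _drop_missing([snp_a, snp_b])
    if len(a) < 2:
        raise ValueError("fewer than 2 jointly non-missing calls")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("monomorphic column: LD r² undefined")
    r = np.corrcoef(a.astype(float), b.astype(float))[0, 1]
    return float(r * r)


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X ≥ k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up at level ``q``; boolean mask per item."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
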