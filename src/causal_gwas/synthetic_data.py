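"""Case-control genotype simulation with planted local-causal structure.

The generator emulates the features a causal-discovery GWAS pipeline must
contend with, at desk scale:

* biallelic SNPs with per-SNP minor-allele frequencies drawn from a range;
* linkage disequilibrium via a first-order haplotype-copying process inside
  fixed-size blocks — within a block each haplotype allele is copied from
  its left neighbour with probability ``ld_rho``, else drawn fresh at that
  SNP's MAF, which yields geometric r² decay with distance;
* a binary phenotype from a logistic model on the dosages of a planted set
  of causal SNPs, with case-control ascertainment by rejection sampling
  (subjects are drawn until the case and control quotas are filled,
  mirroring separate case/control recruitment);
* exact-duplicate SNP columns (complete LD, r² = 1), the mechanism behind
  multiple information-equivalent Markov boundaries;
* missingness applied last — uniform missing-completely-at-random, plus
  phenotype-dependent (not-at-random) extra missingness in cases at chosen
  SNPs.

The accompanying :class:`SyntheticTruth` records the generating structure so
downstream discovery output can be scored against ground truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .gwas_io import MISSING, GenotypeDataset, SNPInfo

#: Default planted per-allele log-odds, strongest to weakest; the default
#: causal set spreads min(5, n_snps) SNPs evenly across the panel.
_DEFAULT_BETAS: tuple[float, ...] = (1.2, 0.9, 0.8, 0.65, 0.5)


def _default_causal(n_snps: int) -> tuple[tuple[int, float], ...]:
    k = min(len(_DEFAULT_BETAS), n_snps)
    idx = [int((j + 0.5) * n_snps / k) for j in range(k)]
    return tuple(zip(idx, _DEFAULT_BETAS[:k]))


@dataclass
class SimulationSpec:
    """Full description of one simulated case-control study."""

    n_cases: int = 1000
    n_controls: int = 1000
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.4
    causal_snps: Optional[tuple[tuple[int, float], ...]] = None  # None -> evenly spread default
    intercept: float = -1.0
    duplicate_pairs: tuple[tuple[int, int], ...] = ()
    missing_mcar_rate: float = 0.0
    nmar_snps: tuple[tuple[int, float], ...] = ()
    seed: int = 0
    max_draw_factor: int = 500  # bounded rejection sampling

    def resolved_causal(self) -> tuple[tuple[int, float], ...]:
        if self.causal_snps is None:
            return _default_causal(self.n_snps)
        return tuple(tuple(c) for c in self.causal_snps)

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if not (0.0 <= self.missing_mcar_rate <= 1.0):
            raise ValueError("missing_mcar_rate must lie in [0, 1]")
        causal = self.resolved_causal()
        idx = [i for i, _ in causal]
        if len(set(idx)) != len(idx):
            raise ValueError("causal SNP indices must be distinct")
        for i, _ in list(causal) + list(self.nmar_snps):
            if not (0 <= i < self.n_snps):
                raise ValueError(f"SNP index {i} out of range")
        for a, b in self.duplicate_pairs:
            if a == b or not (0 <= a < self.n_snps and 0 <= b < self.n_snps):
                raise ValueError(f"invalid duplicate pair ({a}, {b})")
        for _, p in self.nmar_snps:
            if not (0.0 <= p <= 1.0):
                raise ValueError("NMAR extra missing probability must be in [0, 1]")
        if self.ld_block_size < 1 or self.n_snps < 1:
            raise ValueError("n_snps and ld_block_size must be >= 1")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")


@dataclass
class SyntheticTruth:
    """The generating causal structure behind a simulated dataset."""

    causal_effects: dict[str, float]
    equivalence_classes: list[set[str]]
    true_markov_boundaries: list[set[str]]
    missingness_mechanism: dict

    def to_json_dict(self) -> dict:
        return {
            "causal_effects": self.causal_effects,
            "equivalence_classes": [sorted(c) for c in self.equivalence_classes],
            "true_markov_boundaries": [
                sorted(b) for b in self.true_markov_boundaries
            ],
            "missingness_mechanism": self.missingness_mechanism,
        }


def _snp_id(i: int) -> str:
    return f"rs{i + 1:06d}"


def _draw_haplotypes(
    rng: np.random.Generator,
    n_hap: int,
    mafs: np.ndarray,
    block_size: int,
    rho: float,
) -> np.ndarray:
    m = len(mafs)
    fresh = rng.random((n_hap, m)) < mafs
    out = np.empty((n_hap, m), dtype=bool)
    out[:, 0] = fresh[:, 0]
    if m == 1:
        return out
    copy = rng.random((n_hap, m)) < rho
    for j in range(1, m):
        if j % block_size == 0:  # block boundary: no copying across
            out[:, j] = fresh[:, j]
        else:
            out[:, j] = np.where(copy[:, j], out[:, j - 1], fresh[:, j])
    return out


def generate_dataset(spec: SimulationSpec) -> tuple[GenotypeDataset, SyntheticTruth]:
    """Simulate one case-control study; identical spec → identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.maf_range
    mafs = rng.uniform(lo, hi, size=spec.n_snps)

    beta = np.zeros(spec.n_snps)
    causal = spec.resolved_causal()
    for i, b in causal:
        beta[i] = b

    need = spec.n_cases + spec.n_controls
    batch = max(need, 512)
    max_draws = spec.max_draw_factor * need
    drawn = 0
    n_cases = n_controls = 0
    geno_chunks: list[np.ndarray] = []
    pheno_chunks: list[np.ndarray] = []
    while n_cases < spec.n_cases or n_controls < spec.n_controls:
        if drawn >= max_draws:
            raise RuntimeError(
                f"case/control quota unreachable after {drawn} draws "
                "(degenerate intercept/effects?)"
            )
        h1 = _draw_haplotypes(rng, batch, mafs, spec.ld_block_size, spec.ld_rho)
        h2 = _draw_haplotypes(rng, batch, mafs, spec.ld_block_size, spec.ld_rho)
        g = (h1.astype(np.int8) + h2.astype(np.int8))
        for a, b in spec.duplicate_pairs:
            g[:, b] = g[:, a]
        drawn += batch
        p = expit(spec.intercept + g.astype(float) @ beta)
        y = (rng.random(batch) < p).astype(np.int8)
        keep_case = np.flatnonzero(y == 1)[: spec.n_cases - n_cases]
        keep_ctrl = np.flatnonzero(y == 0)[: spec.n_controls - n_controls]
        keep = np.sort(np.concatenate([keep_case, keep_ctrl]))
        geno_chunks.append(g[keep])
        pheno_chunks.append(y[keep])
        n_cases += len(keep_case)
        n_controls += len(keep_ctrl)

    calls = np.concatenate(geno_chunks, axis=0)
    phenotype = np.concatenate(pheno_chunks)

    # missingness applied last
    if spec.missing_mcar_rate > 0:
        mcar = rng.random(calls.shape) < spec.missing_mcar_rate
        calls[mcar] = MISSING
    for i, extra in spec.nmar_snps:
        hit = (rng.random(calls.shape[0]) < extra) & (phenotype == 1)
        calls[hit, i] = MISSING

    snps = [
        SNPInfo(_snp_id(i), "1", (i + 1) * 1000, "A", "G") for i in range(spec.n_snps)
    ]
    subject_ids = [f"S{i + 1:05d}" for i in range(need)]
    ds = GenotypeDataset(calls, snps, subject_ids, phenotype)

    causal_ids = {_snp_id(i): b for i, b in causal}
    classes = _equivalence_classes(spec)
    truth = SyntheticTruth(
        causal_effects=causal_ids,
        equivalence_classes=classes,
        true_markov_boundaries=_boundaries_from(set(causal_ids), classes),
        missingness_mechanism={
            "mcar_rate": spec.missing_mcar_rate,
            "nmar": {_snp_id(i): p for i, p in spec.nmar_snps},
        },
    )
    return ds, truth


def _equivalence_classes(spec: SimulationSpec) -> list[set[str]]:
    """Merge duplicate pairs touching the causal set into equivalence classes."""
    causal = {i for i, _ in spec.resolved_causal()}
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        parent.setdefault(a, a)
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in spec.duplicate_pairs:
        parent[find(a)] = find(b)
    groups: dict[int, set[int]] = {}
    for a in parent:
        groups.setdefault(find(a), set()).add(a)
    classes = [
        {_snp_id(i) for i in grp}
        for grp in groups.values()
        if len(grp) > 1 and grp & causal
    ]
    return sorted(classes, key=lambda c: sorted(c))


def _boundaries_from(
    causal_ids: set[str], classes: Sequence[set[str]]
) -> list[set[str]]:
    relevant = [sorted(c) for c in classes if c & causal_ids]
    if not relevant:
        return [set(causal_ids)]
    base = causal_ids - set().union(*(set(c) for c in relevant))
    out: list[set[str]] = []
    for combo in itertools.product(*relevant):
        bnd = base | set(combo)
        if bnd not in out:
            out.append(bnd)
    return out


def truth_boundaries(truth: SyntheticTruth) -> list[set[str]]:
    """All Markov boundaries implied by the equivalence classes (dedup)."""
    return _boundaries_from(
        set(truth.causal_effects), truth.equivalence_classes
    )
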