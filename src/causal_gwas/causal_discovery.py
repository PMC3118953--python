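"""Markov-boundary induction (GLL-style) and multiple-boundary enumeration (TIE*).

A Markov boundary of the phenotype is a minimal SNP set rendering every
other SNP conditionally independent of the phenotype. The inducer here is a
semi-interleaved inclusion/elimination scheme from the Generalized Local
Learning family:

1. *Prioritization* — every SNP with a reliable, significant marginal G²
   association is a candidate, ordered by ascending p-value (ties broken by
   genomic order).
2. *Interleaved elimination* — candidates are admitted in rank order; after
   each admission every current member ``x`` is tested against all subsets
   ``S`` of the other members with |S| ≤ max-k; if any *reliable* test
   declares ``x ⊥ phenotype | S``, ``x`` is removed and never readmitted.

Because the phenotype has no spouse variables in a GWAS design, the
parents-and-children set equals the Markov boundary and no spouse-recovery
phase is needed.

TIE* wraps the inducer to enumerate every information-equivalent boundary:
it withholds subsets of the discovered boundaries' union (up to a size
cap), re-runs the inducer, and accepts a candidate boundary iff it subsumes
the reference boundary's information — each withheld reference member must
be rendered conditionally independent of the phenotype by some subset of
the candidate. Newly accepted boundaries extend the withheld-subset queue;
the enumeration is deterministic and terminates on the finite capped
lattice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .gwas_io import GenotypeDataset
from .stats_core import CITestResult, g2_test


@dataclass
class DiscoveryConfig:
    """Knobs of the conditional-independence search.

    ``max_k`` caps conditioning-set size (derivable from the sample size via
    :func:`causal_gwas.stats_core.max_conditioning_size`); ``min_avg_cell``
    is the average-count reliability requirement; ``max_equivalence_subset``
    caps the size of the withheld subsets TIE* explores.
    """

    alpha: float = 0.05
    max_k: int = 3
    min_avg_cell: int = 5
    max_equivalence_subset: int = 2

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_k < 0:
            raise ValueError("max_k must be >= 0")


@dataclass
class MarkovBoundary:
    snp_ids: list[str]
    trace: dict[str, dict] = field(default_factory=dict)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.snp_ids)


@dataclass
class TIEOutput:
    boundaries: list[MarkovBoundary]
    shared_core: list[str]
    equivalence_substitutions: list[tuple[list[str], list[str]]]

    def to_json_dict(self) -> dict:
        return {
            "boundaries": [sorted(b.snp_ids) for b in self.boundaries],
            "shared_core": sorted(self.shared_core),
            "equivalence_substitutions": [
                {"removed": sorted(r), "replacement": sorted(a)}
                for r, a in self.equivalence_substitutions
            ],
            "traces": [b.trace for b in self.boundaries],
        }


class _TestCache:
    """Memoized G² tests against the phenotype on one dataset."""

    def __init__(self, ds: GenotypeDataset, cfg: DiscoveryConfig):
        if ds.phenotype is None:
            raise ValueError("discovery requires a phenotype")
        self.ds = ds
        self.cfg = cfg
        self.y = ds.phenotype
        self._cols = {s: ds.calls[:, j] for j, s in enumerate(ds.snp_ids)}
        self._cache: dict[tuple[str, frozenset[str]], CITestResult] = {}
        self.n_tests = 0

    def test(self, x: str, cond: frozenset[str]) -> CITestResult:
        key = (x, cond)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        res = g2_test(
            self.y,
            self._cols[x],
            [self._cols[z] for z in sorted(cond)],
            alpha=self.cfg.alpha,
            min_avg_cell=self.cfg.min_avg_cell,
        )
        self._cache[key] = res
        self.n_tests += 1
        return res


def _genomic_key(ds: GenotypeDataset) -> dict[str, tuple]:
    return {
        s.snp_id: (s.chromosome, s.position, s.snp_id) for s in ds.snps
    }


def rank_candidates(
    ds: GenotypeDataset,
    cfg: DiscoveryConfig | None = None,
    _cache: Optional[_TestCache] = None,
) -> list[str]:
    """SNPs with reliable marginal G² dependence at α, by ascending p-value.

    Ties break on ascending (chromosome, position).
    """
    cfg = cfg or DiscoveryConfig()
    cfg.validate()
    cache = _cache or _TestCache(ds, cfg)
    gkey = _genomic_key(ds)
    hits: list[tuple[float, tuple, str]] = []
    for s in ds.snp_ids:
        res = cache.test(s, frozenset())
        if res.reliable and res.independent is False:
            hits.append((res.p_value, gkey[s], s))
    hits.sort(key=lambda t: (t[0], t[1]))
    return [s for _, _, s in hits]


def _subsets(items: Sequence[str], max_size: int) -> Iterable[tuple[str, ...]]:
    """Subsets in increasing size, lexicographic within size."""
    ordered = sorted(items)
    for k in range(min(max_size, len(ordered)) + 1):
        yield from itertools.combinations(ordered, k)


def gll_mb(
    ds: GenotypeDataset,
    cfg: DiscoveryConfig | None = None,
    withhold: frozenset[str] = frozenset(),
    _cache: Optional[_TestCache] = None,
    _ranked: Optional[list[str]] = None,
) -> MarkovBoundary:
    """Induce one Markov boundary of the phenotype.

    ``withhold`` removes SNPs from consideration (used by TIE*).
    """
    cfg = cfg or DiscoveryConfig()
    cfg.validate()
    cache = _cache or _TestCache(ds, cfg)
    ranked = _ranked if _ranked is not None else rank_candidates(ds, cfg, _cache=cache)
    candidates = [s for s in ranked if s not in withhold]

    members: list[str] = []
    trace: dict[str, dict] = {}
    eliminated: set[str] = set()

    def sweep() -> None:
        changed = True
        while changed:
            changed = False
            for x in list(members):
                others = [m for m in members if m != x]
                for sub in _subsets(others, cfg.max_k):
                    res = cache.test(x, frozenset(sub))
                    if res.reliable and res.independent:
                        members.remove(x)
                        eliminated.add(x)
                        trace[x] = {
                            "status": "eliminated",
                            "given": list(sub),
                            "p_value": res.p_value,
                        }
                        changed = True
                        break
                if changed:
                    break

    for s in candidates:
        if s in eliminated:
            continue
        members.append(s)
        marg = cache.test(s, frozenset())
        trace.setdefault(s, {"status": "admitted", "p_value": marg.p_value})
        sweep()

    gkey = _genomic_key(ds)
    members.sort(key=lambda s: gkey[s])
    for s in members:
        trace[s]["status"] = "member"
    return MarkovBoundary(members, trace)


def verify_equivalence(
    m_ref: MarkovBoundary | Sequence[str],
    m_new: MarkovBoundary | Sequence[str],
    ds: GenotypeDataset,
    cfg: DiscoveryConfig | None = None,
    _cache: Optional[_TestCache] = None,
) -> bool:
    """Does ``m_new`` subsume the information in ``m_ref``?

    True iff every SNP of ``m_ref`` missing from ``m_new`` is rendered
    conditionally independent of the phenotype by some subset of ``m_new``
    (|S| ≤ max-k, reliable test).
    """
    cfg = cfg or DiscoveryConfig()
    cache = _cache or _TestCache(ds, cfg)
    ref = set(m_ref.snp_ids if isinstance(m_ref, MarkovBoundary) else m_ref)
    new = set(m_new.snp_ids if isinstance(m_new, MarkovBoundary) else m_new)
    for x in sorted(ref - new):
        found = False
        for sub in _subsets(sorted(new), cfg.max_k):
            res = cache.test(x, frozenset(sub))
            if res.reliable and res.independent:
                found = True
                break
        if not found:
            return False
    return True


def tie_star(
    ds: GenotypeDataset, cfg: DiscoveryConfig | None = None
) -> TIEOutput:
    """Enumerate all information-equivalent Markov boundaries of the phenotype."""
    cfg = cfg or DiscoveryConfig()
    cfg.validate()
    cache = _TestCache(ds, cfg)
    ranked = rank_candidates(ds, cfg, _cache=cache)

    m0 = gll_mb(ds, cfg, _cache=cache, _ranked=ranked)
    boundaries = [m0]
    seen = {m0.as_set()}

    processed: set[frozenset[str]] = set()
    while True:
        union = sorted(set().union(*(b.as_set() for b in boundaries)))
        pending = None
        for k in range(1, cfg.max_equivalence_subset + 1):
            for combo in itertools.combinations(union, k):
                g = frozenset(combo)
                if g not in processed:
                    pending = g
                    break
            if pending is not None:
                break
        if pending is None:
            break
        processed.add(pending)
        mg = gll_mb(ds, cfg, withhold=pending, _cache=cache, _ranked=ranked)
        if mg.as_set() in seen:
            continue
        if verify_equivalence(m0, mg, ds, cfg, _cache=cache):
            boundaries.append(mg)
            seen.add(mg.as_set())

    core = set(boundaries[0].snp_ids)
    for b in boundaries[1:]:
        core &= b.as_set()
    substitutions = [
        (sorted(m0.as_set() - b.as_set()), sorted(b.as_set() - m0.as_set()))
        for b in boundaries[1:]
    ]
    return TIEOutput(boundaries, sorted(core), substitutions)
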