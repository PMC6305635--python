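"""EM estimation of haplotype frequencies from unphased diploid genotypes.

With multi-site genotypes of unknown gametic phase, a heterozygote at k
sites is compatible with 2^(k-1) unordered haplotype pairs.  Under
Hardy-Weinberg equilibrium the sample likelihood is

    L(p) = prod_g  sum_{(h1,h2) ~ g} (2 - delta_{h1 h2}) p_{h1} p_{h2}

and the EM algorithm iterates: E-step, posterior weights over each
individual's compatible pairs proportional to (2 - delta) p_{h1} p_{h2};
M-step, p_i = E[count of haplotype i] / 2n.  Missing genotype calls are
summed over inside the pair enumeration rather than dropping individuals.

The support is restricted to haplotypes compatible with at least one
individual.  Restart 1 starts from the uniform distribution over that
support (deterministic); further restarts draw Dirichlet(1) starting
points from the configured seed, to escape symmetric saddle points such
as a lone double heterozygote.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .haplotype_core import (
    DEFAULT_SITE_MAP,
    GenotypeRecord,
    Haplotype,
    HaplotypeError,
    SiteMap,
    format_haplotype,
)

__all__ = [
    "PhaseConfig",
    "EMResult",
    "enumerate_compatible_pairs",
    "log_likelihood",
    "em_estimate",
    "write_em_result",
]

logger = logging.getLogger(__name__)

#: Frequencies below this are removed from the reported support.
_SUPPORT_EPS = 1e-12


@dataclass(frozen=True)
class PhaseConfig:
    """EM run settings.

    Attributes
    ----------
    tol
        Convergence tolerance on the absolute change in log-likelihood.
    max_iter
        Iteration cap per restart.
    restarts
        Number of EM restarts; the first is uniform, the rest Dirichlet(1).
    seed
        Seed for the random restarts.
    """

    tol: float = 1e-8
    max_iter: int = 10_000
    restarts: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class EMResult:
    """Maximum-likelihood haplotype frequencies and diagnostics."""

    haplotypes: list[Haplotype]
    frequencies: np.ndarray
    log_likelihood: float
    iterations: int
    converged: bool

    def as_dict(self) -> dict[Haplotype, float]:
        return {h: float(p) for h, p in zip(self.haplotypes, self.frequencies)}


def _site_options(count: int | None) -> list[tuple[int, int]]:
    """Ordered allele pairs consistent with one site's diploid count."""
    if count == 0:
        return [(0, 0)]
    if count == 2:
        return [(1, 1)]
    if count == 1:
        return [(0, 1), (1, 0)]
    # missing: sum over all four ordered allele pairs
    return [(0, 0), (0, 1), (1, 0), (1, 1)]


def enumerate_compatible_pairs(
    g: GenotypeRecord,
) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered haplotype pairs whose allele counts reproduce ``g``.

    Missing sites are summed over both alleles.  For a record heterozygous
    at k sites with no missing data the list has max(1, 2^(k-1)) entries.
    Pairs are returned as (state-tuple, state-tuple) with the two members
    in lexicographic order, the list itself sorted for determinism.
    """
    options = [_site_options(c) for c in g.counts]
    pairs: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
    for combo in itertools.product(*options):
        h1 = tuple(a for a, _ in combo)
        h2 = tuple(b for _, b in combo)
        pairs.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(pairs)


def log_likelihood(
    p: dict[tuple[int, ...], float] | dict[Haplotype, float],
    sample: list[GenotypeRecord],
) -> float:
    """Multinomial HWE log-likelihood of ``sample`` under frequencies ``p``.

    Returns ``-inf`` if any individual has zero total probability over its
    compatible pairs.
    """
    freqs = {
        (k.states if isinstance(k, Haplotype) else tuple(k)): float(v)
        for k, v in p.items()
    }
    total = 0.0
    for g in sample:
        prob = 0.0
        for h1, h2 in enumerate_compatible_pairs(g):
            coef = 1.0 if h1 == h2 else 2.0
            prob += coef * freqs.get(h1, 0.0) * freqs.get(h2, 0.0)
        if prob <= 0.0:
            return float("-inf")
        total += np.log(prob)
    return float(total)


def _compile_sample(sample: list[GenotypeRecord]):
    """Group identical genotypes and index their pair lists into the support.

    Returns (support, groups) where support is the sorted list of state
    tuples occurring in any compatible pair, and each group is
    (count, idx1, idx2, coef) arrays for one distinct genotype.
    """
    counts: dict[tuple, int] = {}
    for g in sample:
        counts[g.counts] = counts.get(g.counts, 0) + 1
    pair_lists = {key: enumerate_compatible_pairs(GenotypeRecord(key)) for key in counts}
    support = sorted({h for pairs in pair_lists.values() for hp in pairs for h in hp})
    index = {h: i for i, h in enumerate(support)}
    groups = []
    # missing calls (None) sort below 0 for a deterministic group order
    for key, n_g in sorted(
        counts.items(), key=lambda kv: tuple(-1 if c is None else c for c in kv[0])
    ):
        pairs = pair_lists[key]
        i1 = np.array([index[a] for a, _ in pairs], dtype=np.intp)
        i2 = np.array([index[b] for _, b in pairs], dtype=np.intp)
        coef = np.where(i1 == i2, 1.0, 2.0)
        groups.append((n_g, i1, i2, coef))
    return support, groups


def _em_run(p0: np.ndarray, groups, n_ind: int, config: PhaseConfig):
    """One EM trajectory from starting point ``p0``; returns (p, ll, it, conv)."""
    p = p0.copy()
    prev_ll = -np.inf
    for it in range(1, config.max_iter + 1):
        expected = np.zeros_like(p)
        ll = 0.0
        for n_g, i1, i2, coef in groups:
            w = coef * p[i1] * p[i2]
            tot = w.sum()
            if tot <= 0.0:
                return p, float("-inf"), it, False
            ll += n_g * np.log(tot)
            w *= n_g / tot
            np.add.at(expected, i1, w)
            np.add.at(expected, i2, w)
        p = expected / (2 * n_ind)
        if abs(ll - prev_ll) < config.tol:
            return p, float(ll), it, True
        prev_ll = ll
    return p, float(prev_ll), config.max_iter, False


def em_estimate(
    sample: list[GenotypeRecord], config: PhaseConfig = PhaseConfig()
) -> EMResult:
    """Maximum-likelihood haplotype frequencies for an unphased sample.

    Runs ``config.restarts`` EM trajectories and returns the one with the
    best final log-likelihood (ties broken by first occurrence).
    Haplotypes whose fitted frequency falls below 1e-12 are dropped from
    the reported support.

    Raises
    ------
    HaplotypeError
        If the sample is empty or record lengths are inconsistent.
    """
    if not sample:
        raise HaplotypeError("cannot estimate frequencies from an empty sample")
    lengths = {len(g) for g in sample}
    if len(lengths) != 1:
        raise HaplotypeError(f"inconsistent genotype lengths: {sorted(lengths)}")

    support, groups = _compile_sample(sample)
    n_ind = len(sample)
    k = len(support)
    rng = np.random.default_rng(config.seed)

    best = None
    for r in range(config.restarts):
        if r == 0:
            p0 = np.full(k, 1.0 / k)
        else:
            p0 = rng.dirichlet(np.ones(k))
        p, ll, it, conv = _em_run(p0, groups, n_ind, config)
        logger.debug("EM restart %d: ll=%.6f iter=%d converged=%s", r, ll, it, conv)
        if best is None or ll > best[1]:
            best = (p, ll, it, conv)

    p, ll, it, conv = best
    keep = p >= _SUPPORT_EPS
    p = p[keep]
    p = p / p.sum()
    haps = [Haplotype(h) for h, k_ in zip(support, keep) if k_]
    return EMResult(
        haplotypes=haps,
        frequencies=p,
        log_likelihood=ll,
        iterations=it,
        converged=conv,
    )


def write_em_result(
    result: EMResult,
    path: str | Path,
    site_map: SiteMap = DEFAULT_SITE_MAP,
    population: str = "frequency",
) -> None:
    """Write an :class:`EMResult` as TSV (``haplotype``, ``pattern``, frequency)."""
    import pandas as pd

    order = np.argsort(-result.frequencies)
    df = pd.DataFrame(
        {
            "haplotype": [
                result.haplotypes[i].label or f"H{j + 1}" for j, i in enumerate(order)
            ],
            "pattern": [format_haplotype(result.haplotypes[i], sep="") for i in order],
            population: np.round(result.frequencies[order], 6),
        }
    )
    df.to_csv(path, sep="\t", index=False)
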