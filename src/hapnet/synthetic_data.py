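"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators make every stage testable without external data:

* :func:`simulate_genotypes` draws, for each diploid individual, two
  haplotypes independently from a frequency vector (Hardy-Weinberg random
  union) and erases phase, leaving site-wise allele counts — the kind of
  unphased sample the EM stage consumes.

* :func:`simulate_star` drops a Poisson(lambda) number of mutations on
  each of n independent lineages radiating from a known ancestral
  haplotype (a star genealogy).  By default mutated sites are drawn
  without replacement within a lineage (infinite-sites approximation), so
  the observed Hamming distance to the root equals the true mutation
  count and rho validation is exact; recurrent mutation is available
  behind a flag for robustness testing.

Both generators are fully deterministic under their seed.  The module
also ships the published world-population frequency table and age table
as packaged fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .haplotype_core import (
    DEFAULT_SITE_MAP,
    FrequencyTable,
    GenotypeRecord,
    Haplotype,
    HaplotypeError,
    SiteMap,
    load_frequency_table,
)

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_star",
    "world_frequency_table",
    "published_age_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Settings for the generators.

    ``n``: individuals (genotypes) or chromosomes (star); ``L``: haplotype
    length; ``lam``: expected mutations per lineage; ``freqs``: generating
    haplotype frequency vector for genotype simulation.
    """

    seed: int = 0
    n: int = 100
    L: int = 7
    lam: float = 3.0
    freqs: tuple[tuple[tuple[int, ...], float], ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


def _normalise_freqs(freqs) -> tuple[list[tuple[int, ...]], np.ndarray]:
    if isinstance(freqs, dict):
        items = sorted(freqs.items(), key=lambda kv: (
            kv[0].states if isinstance(kv[0], Haplotype) else tuple(kv[0])
        ))
    else:
        items = list(freqs)
    haps = [
        h.states if isinstance(h, Haplotype) else tuple(h) for h, _ in items
    ]
    p = np.array([float(v) for _, v in items], dtype=float)
    if len(haps) == 0:
        raise HaplotypeError("empty frequency vector")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=0.005):
        raise HaplotypeError(f"frequencies must be >= 0 and sum to 1 (sum={p.sum():.4f})")
    if len({len(h) for h in haps}) != 1:
        raise HaplotypeError("haplotypes must share one length")
    return haps, p / p.sum()


def simulate_genotypes(
    freqs, n: int, seed: int = 0
) -> list[GenotypeRecord]:
    """Unphased diploid genotypes under Hardy-Weinberg random union.

    Each individual is two independent haplotype draws from ``freqs``
    (a ``{haplotype: frequency}`` mapping or (haplotype, frequency)
    sequence), reduced to per-site counts of the ``+`` allele.
    """
    if n < 1:
        raise HaplotypeError("n must be >= 1")
    haps, p = _normalise_freqs(freqs)
    rng = np.random.default_rng(seed)
    mat = np.array(haps, dtype=int)
    draws = rng.choice(len(haps), size=(n, 2), p=p)
    counts = mat[draws[:, 0]] + mat[draws[:, 1]]
    return [
        GenotypeRecord(tuple(int(c) for c in row), individual=f"sim{i + 1}")
        for i, row in enumerate(counts)
    ]


def simulate_star(
    root: Haplotype | tuple[int, ...],
    n: int,
    lam: float,
    seed: int = 0,
    infinite_sites: bool = True,
    mutation_counts: list[int] | None = None,
) -> tuple[list[Haplotype], list[int]]:
    """Mutation accumulation on a star genealogy from a known ancestor.

    Each of ``n`` lineages receives a Poisson(``lam``) number of site
    flips (or the deterministic ``mutation_counts`` override).  Under the
    default infinite-sites approximation a lineage's mutated sites are
    drawn without replacement, so its Hamming distance to the root equals
    its true mutation count; if a lineage draws more mutations than there
    are sites (or ``infinite_sites=False``), sites are drawn with
    replacement and a back-mutation warning is logged.

    Returns the observed haplotypes and the true per-lineage mutation
    counts.
    """
    r = root.states if isinstance(root, Haplotype) else tuple(root)
    L = len(r)
    if L < 1:
        raise HaplotypeError("root haplotype must have at least one site")
    if lam < 0:
        raise HaplotypeError("lam must be >= 0")
    rng = np.random.default_rng(seed)
    if mutation_counts is not None:
        if len(mutation_counts) != n:
            raise HaplotypeError("mutation_counts must have one entry per lineage")
        counts = [int(k) for k in mutation_counts]
    else:
        counts = [int(k) for k in rng.poisson(lam, size=n)]

    haps: list[Haplotype] = []
    for i, k in enumerate(counts):
        states = list(r)
        if infinite_sites and k <= L:
            sites = rng.choice(L, size=k, replace=False)
        else:
            if k > 0:
                logger.warning(
                    "lineage %d: %d mutations on %d sites drawn with replacement; "
                    "back-mutation possible, observed distance may undercount",
                    i,
                    k,
                    L,
                )
            sites = rng.choice(L, size=k, replace=True)
        for s in sites:
            states[s] = 1 - states[s]
        haps.append(Haplotype(tuple(states), label=f"lin{i + 1}"))
    return haps, counts


def _data_path(name: str):
    return resources.files("hapnet.data").joinpath(name)


def world_frequency_table(site_map: SiteMap = DEFAULT_SITE_MAP) -> FrequencyTable:
    """The packaged world-population haplotype frequency table.

    21 haplotypes (HAP1-HAP21) by 8 populations (Turkey, Iran, India,
    Thailand, Italia, Holland, Belgium, Mexico), shipped verbatim from
    the published table.
    """
    with resources.as_file(_data_path("world_haplotype_frequencies.tsv")) as p:
        return load_frequency_table(p, site_map)


def published_age_table() -> pd.DataFrame:
    """The published per-haplotype age estimates (rho/sigma and years).

    One row per non-ancestral haplotype with columns ``label``,
    ``pattern``, ``years``, ``years_sd``, ``rho``, ``sigma``, shipped
    verbatim; the ancestral all-minus haplotype has no age row.
    """
    with resources.as_file(_data_path("published_age_estimates.tsv")) as p:
        return pd.read_csv(p, sep="\t")
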