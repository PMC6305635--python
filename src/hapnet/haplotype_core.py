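"""Core data model for restriction-site haplotypes.

A haplotype here is an ordered binary vector over polymorphic restriction
sites in the beta-globin gene cluster: ``1`` means the enzyme cuts at the
site (``+`` in the classical RFLP notation), ``0`` means it does not
(``-``).  The default site map covers the seven classical sites, in the
fixed order that defines every vector index in the package:

    HincII 5' to epsilon, HindIII G-gamma, HindIII A-gamma, HincII psi-beta,
    HincII 3' to psi-beta, AvaII beta, HinfI 3' to beta.

The module also handles parsing/formatting of the ``+``/``-`` pattern
notation, Hamming distances (mutational steps), and reading/writing of
haplotype-frequency tables and unphased genotype tables as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteMap",
    "Haplotype",
    "FrequencyTable",
    "GenotypeRecord",
    "DEFAULT_SITE_MAP",
    "parse_haplotype",
    "format_haplotype",
    "hamming_distance",
    "load_frequency_table",
    "write_frequency_table",
    "load_genotypes",
    "write_genotypes",
    "HaplotypeError",
]

#: Unicode minus, as used in the source tables; normalised to ASCII on input.
_UNICODE_MINUS = "−"

#: Characters accepted for the two allelic states.
_PLUS_CHARS = frozenset("+1")
_MINUS_CHARS = frozenset({"-", "0", _UNICODE_MINUS})


class HaplotypeError(ValueError):
    """Raised for malformed patterns, tables or genotype records."""


@dataclass(frozen=True)
class SiteMap:
    """Ordered list of restriction-site labels; fixes all vector indices.

    Parameters
    ----------
    sites
        Site labels, one per polymorphic restriction site.  Order is
        positional and fixed; labels must be unique.
    """

    sites: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise HaplotypeError("a SiteMap needs at least one site")
        if len(set(self.sites)) != len(self.sites):
            raise HaplotypeError("site labels must be unique")

    @property
    def L(self) -> int:
        return len(self.sites)


#: The seven classical beta-globin cluster RFLP sites, 5' to 3'.
DEFAULT_SITE_MAP = SiteMap(
    sites=(
        "HincII-5'epsilon",
        "HindIII-Ggamma",
        "HindIII-Agamma",
        "HincII-psibeta",
        "HincII-3'psibeta",
        "AvaII-beta",
        "HinfI-3'beta",
    )
)


@dataclass(frozen=True)
class Haplotype:
    """Binary state vector over the sites of a :class:`SiteMap`.

    Equality and hashing use the state vector only, so haplotypes with
    different labels but the same pattern compare equal.
    """

    states: tuple[int, ...]
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if any(s not in (0, 1) for s in self.states):
            raise HaplotypeError(f"haplotype states must be 0/1, got {self.states!r}")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def pattern(self) -> str:
        """Compact ASCII pattern, e.g. ``'-++-+++'``."""
        return format_haplotype(self, sep="")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        name = f" {self.label}" if self.label else ""
        return f"<Haplotype{name} {self.pattern}>"


def parse_haplotype(
    text: str, site_map: SiteMap = DEFAULT_SITE_MAP, label: str | None = None
) -> Haplotype:
    """Parse a ``+``/``-`` pattern (or 0/1 string) into a :class:`Haplotype`.

    Whitespace is ignored; both the ASCII hyphen and the Unicode minus are
    accepted for the absent state.  The pattern must contain exactly one
    symbol per site of ``site_map``.

    Raises
    ------
    HaplotypeError
        If the symbol count is wrong or a character is not a valid state,
        naming the offending position.
    """
    symbols = [c for c in text if not c.isspace()]
    if len(symbols) != site_map.L:
        raise HaplotypeError(
            f"expected {site_map.L} site symbols, got {len(symbols)} in {text!r}"
        )
    states = []
    for pos, c in enumerate(symbols):
        if c in _PLUS_CHARS:
            states.append(1)
        elif c in _MINUS_CHARS:
            states.append(0)
        else:
            raise HaplotypeError(
                f"invalid state character {c!r} at position {pos} in {text!r}"
            )
    return Haplotype(states=tuple(states), label=label)


def format_haplotype(h: Haplotype | Sequence[int], sep: str = " ") -> str:
    """Format a haplotype as its ``+``/``-`` pattern (always ASCII)."""
    states = h.states if isinstance(h, Haplotype) else tuple(h)
    return sep.join("+" if s else "-" for s in states)


def hamming_distance(a: Haplotype | Sequence[int], b: Haplotype | Sequence[int]) -> int:
    """Number of sites at which two haplotypes differ (mutational steps)."""
    sa = a.states if isinstance(a, Haplotype) else tuple(a)
    sb = b.states if isinstance(b, Haplotype) else tuple(b)
    if len(sa) != len(sb):
        raise HaplotypeError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return sum(x != y for x, y in zip(sa, sb))


@dataclass
class FrequencyTable:
    """Haplotype-by-population matrix of relative frequencies.

    ``values[i, j]`` is the frequency of ``haplotypes[i]`` in
    ``populations[j]``.  Columns of a valid table sum to 1 within a
    tolerance that absorbs the 3-4 significant-digit rounding of published
    tables; all-zero columns (population not typed for this haplotype set)
    are permitted and skipped by validation.
    """

    haplotypes: list[Haplotype]
    populations: list[str]
    values: np.ndarray
    site_map: SiteMap = DEFAULT_SITE_MAP

    #: Column-sum tolerance; published columns sum to ~0.9997 after rounding.
    COLUMN_SUM_TOL = 0.005

    def validate(self, tol: float | None = None) -> None:
        tol = self.COLUMN_SUM_TOL if tol is None else tol
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.haplotypes), len(self.populations)):
            raise HaplotypeError(
                f"value matrix shape {vals.shape} does not match "
                f"{len(self.haplotypes)} haplotypes x {len(self.populations)} populations"
            )
        if np.any(vals < 0) or np.any(vals > 1):
            raise HaplotypeError("frequencies must lie in [0, 1]")
        patterns = [h.states for h in self.haplotypes]
        if len(set(patterns)) != len(patterns):
            raise HaplotypeError("duplicate haplotype patterns in table")
        bad = []
        for j, pop in enumerate(self.populations):
            col = vals[:, j]
            if not np.any(col > 0):
                continue  # absent population: permitted
            s = col.sum()
            if not (1 - tol <= s <= 1 + tol):
                bad.append(f"{pop} (sum={s:.4f})")
        if bad:
            raise HaplotypeError(
                "population columns do not sum to 1 within "
                f"{tol}: {', '.join(bad)}"
            )

    def column(self, population: str) -> dict[Haplotype, float]:
        """Frequency vector of one population as a haplotype -> value map."""
        j = self.populations.index(population)
        return {
            h: float(v) for h, v in zip(self.haplotypes, self.values[:, j]) if v > 0
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.populations)
        df.insert(0, "pattern", [h.pattern for h in self.haplotypes])
        df.insert(0, "label", [h.label or "" for h in self.haplotypes])
        return df


def load_frequency_table(
    path: str | Path, site_map: SiteMap = DEFAULT_SITE_MAP
) -> FrequencyTable:
    """Read a frequency TSV (``label``, ``pattern``, one column per population).

    The table is validated on load: frequencies in [0, 1], unique patterns,
    and every nonzero population column summing to 1 within the tolerance.
    """
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "pattern": str})
    for col in ("label", "pattern"):
        if col not in df.columns:
            raise HaplotypeError(f"frequency table missing required column {col!r}")
    populations = [c for c in df.columns if c not in ("label", "pattern")]
    if not populations:
        raise HaplotypeError("frequency table has no population columns")
    haplotypes = [
        parse_haplotype(pat, site_map, label=lab)
        for lab, pat in zip(df["label"], df["pattern"])
    ]
    values = df[populations].to_numpy(dtype=float)
    table = FrequencyTable(haplotypes, populations, values, site_map)
    table.validate()
    return table


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    """Write a :class:`FrequencyTable` back to TSV (ASCII patterns)."""
    table.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GenotypeRecord:
    """Unphased diploid genotype: per-site count of the ``+`` allele.

    Each entry is 0, 1 or 2 copies of the cut (``+``) state, or ``None``
    for a missing call.  No gametic phase is recorded.
    """

    counts: tuple[int | None, ...]
    individual: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if any(c is not None and c not in (0, 1, 2) for c in self.counts):
            raise HaplotypeError(f"genotype counts must be 0/1/2/None: {self.counts!r}")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def heterozygous_sites(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.counts) if c == 1)

    @property
    def missing_sites(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.counts) if c is None)


_GT_TO_COUNT = {"+/+": 2, "+/-": 1, "-/+": 1, "-/-": 0, "./.": None}
_COUNT_TO_GT = {2: "+/+", 1: "+/-", 0: "-/-", None: "./."}


def load_genotypes(
    path: str | Path, site_map: SiteMap = DEFAULT_SITE_MAP
) -> list[GenotypeRecord]:
    """Read an unphased genotype TSV (``individual`` + one column per site).

    Cell values are ``+/+``, ``+/-``, ``-/-`` or ``./.`` (missing);
    Unicode minus is normalised to ASCII.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "individual" not in df.columns:
        raise HaplotypeError("genotype table missing 'individual' column")
    site_cols = [c for c in df.columns if c != "individual"]
    if len(site_cols) != site_map.L:
        raise HaplotypeError(
            f"expected {site_map.L} site columns, found {len(site_cols)}"
        )
    records = []
    for _, row in df.iterrows():
        counts = []
        for c in site_cols:
            cell = str(row[c]).strip().replace(_UNICODE_MINUS, "-")
            if cell not in _GT_TO_COUNT:
                raise HaplotypeError(
                    f"invalid genotype value {cell!r} for individual "
                    f"{row['individual']!r}, site {c!r}"
                )
            counts.append(_GT_TO_COUNT[cell])
        records.append(GenotypeRecord(tuple(counts), individual=str(row["individual"])))
    return records


def write_genotypes(
    records: Iterable[GenotypeRecord],
    path: str | Path,
    site_map: SiteMap = DEFAULT_SITE_MAP,
    header_comment: str | None = None,
) -> None:
    """Write genotype records as TSV in the dialect read by :func:`load_genotypes`."""
    records = list(records)
    rows = []
    for i, rec in enumerate(records):
        row = {"individual": rec.individual or f"ind{i + 1}"}
        for site, c in zip(site_map.sites, rec.counts):
            row[site] = _COUNT_TO_GT[c]
        rows.append(row)
    df = pd.DataFrame(rows, columns=["individual", *site_map.sites])
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
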