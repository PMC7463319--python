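"""Data model and I/O for diploid codominant (microsatellite) genotypes.

The central container is :class:`GenotypeMatrix`: individuals x loci, each
call an unordered pair of integer allele sizes (fragment lengths in base
pairs) or missing.  Populations are text codes attached per individual and
drawn from the sampling-site list.  File formats supported are the GenePop
dialect (the lingua franca of microsatellite software) and a plain
delimiter-separated table with one row per individual and "a/b" genotype
columns.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Marker",
    "SiteInfo",
    "GenotypeMatrix",
    "AlleleFrequencyTable",
    "GenePopParseError",
    "read_genepop",
    "write_genepop",
    "read_genotype_table",
    "write_genotype_table",
    "read_site_table",
    "find_clones",
    "dedup_clones",
    "allele_frequencies",
]

#: sentinel used internally for a missing allele call
MISSING = -1


@dataclass(frozen=True)
class Marker:
    """A codominant locus scored as integer fragment lengths (bp).

    ``missing_code`` is the on-disk sentinel (``0`` in GenePop); internally
    missing calls are stored as ``-1`` which can never collide with a
    fragment length.
    """

    name: str
    missing_code: int = 0

    def __post_init__(self) -> None:
        if self.missing_code < 0:
            raise ValueError("missing code must be a non-negative integer")


@dataclass(frozen=True)
class SiteInfo:
    """A sampling site: code, WGS84 coordinates and census size.

    Census size is kept as text because field estimates are often ranges
    ("100s", ">500"); :attr:`census_numeric` extracts a best-effort number.
    """

    code: str
    latitude: float
    longitude: float
    census: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range for site {self.code!r}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range for site {self.code!r}")

    @property
    def census_numeric(self) -> float:
        digits = "".join(c for c in str(self.census) if c.isdigit() or c == ".")
        try:
            return float(digits)
        except ValueError:
            return float("nan")


class GenePopParseError(ValueError):
    """Raised when a GenePop file cannot be parsed; carries the line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class GenotypeMatrix:
    """Diploid multi-locus genotypes with population labels.

    Parameters
    ----------
    ids
        One identifier per individual.
    pops
        Population (site) code per individual.
    loci
        Locus names or :class:`Marker` objects, one per locus.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele sizes
        in base pairs, ``-1`` for missing.  Calls are unordered pairs: the
        two slots are sorted on construction so ``a/b`` equals ``b/a``.
    """

    def __init__(
        self,
        ids: Sequence[str],
        pops: Sequence[str],
        loci: Sequence[Marker | str],
        calls: np.ndarray,
    ):
        self.ids = list(map(str, ids))
        self.pops = np.asarray(pops, dtype=object)
        self.loci = [m if isinstance(m, Marker) else Marker(str(m)) for m in loci]
        calls = np.asarray(calls, dtype=np.int64)
        if calls.ndim != 3 or calls.shape[2] != 2:
            raise ValueError("calls must have shape (n_individuals, n_loci, 2)")
        if calls.shape[0] != len(self.ids) or calls.shape[1] != len(self.loci):
            raise ValueError("calls shape inconsistent with ids/loci")
        if len(self.ids) != len(self.pops):
            raise ValueError("ids and pops must have equal length")
        bad = (calls <= 0) & (calls != MISSING)
        if bad.any():
            raise ValueError("allele sizes must be strictly positive (or -1 missing)")
        # a genotype is missing as a whole: if either slot is missing, both are
        half = (calls == MISSING).sum(axis=2) == 1
        calls = calls.copy()
        calls[half] = MISSING
        self.calls = np.sort(calls, axis=2)  # unordered-pair canonical form

    # -- basic protocol ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [m.name for m in self.loci]

    @property
    def populations(self) -> list[str]:
        """Population codes in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask: True where the genotype is missing."""
        return self.calls[:, :, 0] == MISSING

    def __len__(self) -> int:
        return self.n_individuals

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and list(self.pops) == list(other.pops)
            and self.locus_names == other.locus_names
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_individuals} individuals, "
            f"{self.n_loci} loci, {len(self.populations)} populations)"
        )

    # -- manipulation ------------------------------------------------------
    def subset(self, indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        return GenotypeMatrix(
            [self.ids[i] for i in idx], self.pops[idx], self.loci, self.calls[idx]
        )

    def by_population(self, pop: str) -> "GenotypeMatrix":
        return self.subset(np.flatnonzero(self.pops == pop))

    @staticmethod
    def concat(parts: Iterable["GenotypeMatrix"]) -> "GenotypeMatrix":
        parts = list(parts)
        names = parts[0].locus_names
        if any(p.locus_names != names for p in parts):
            raise ValueError("cannot concatenate matrices with different loci")
        return GenotypeMatrix(
            list(itertools.chain.from_iterable(p.ids for p in parts)),
            np.concatenate([p.pops for p in parts]),
            parts[0].loci,
            np.concatenate([p.calls for p in parts], axis=0),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """One row per individual; genotype columns formatted ``a/b``."""
        cols: dict[str, list] = {"id": self.ids, "pop": list(self.pops)}
        for j, name in enumerate(self.locus_names):
            col = []
            for i in range(self.n_individuals):
                a, b = self.calls[i, j]
                col.append("." if a == MISSING else f"{a}/{b}")
            cols[name] = col
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# GenePop I/O


def _parse_genepop_allele(token: str, width: int, line: int) -> tuple[int, int]:
    if len(token) != 2 * width or not token.isdigit():
        raise GenePopParseError(
            f"genotype token {token!r} is not {2 * width} digits", line
        )
    a, b = int(token[:width]), int(token[width:])
    return (MISSING if a == 0 else a, MISSING if b == 0 else b)


def read_genepop(path: str | Path | io.TextIOBase) -> GenotypeMatrix:
    """Read a GenePop file (2- or 3-digit alleles, ``Pop`` separators).

    ``000`` / ``000000`` codes parse as missing.  Populations are labelled
    ``pop1`` .. ``popK`` in file order unless the first individual name in a
    population block looks like a site code, in which case that prefix is
    used (the common ``CODE_01 ,`` convention).
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenePopParseError("empty file", 1)

    # header line 1 is a free-text title; then locus names until first "Pop"
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        raw = lines[i].strip()
        if not raw:
            i += 1
            continue
        # locus names may be comma-separated on one line
        loci.extend(s.strip() for s in raw.split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenePopParseError("no 'Pop' separator found", len(lines))
    if not loci:
        raise GenePopParseError("no locus names before first 'Pop'", i + 1)

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_index = 0
    pop_label: str | None = None
    width: int | None = None
    while i < len(lines):
        raw = lines[i].strip()
        if not raw:
            i += 1
            continue
        if raw.lower() == "pop":
            pop_index += 1
            pop_label = None
            i += 1
            continue
        if "," not in raw:
            raise GenePopParseError("expected 'name , genotypes' record", i + 1)
        name, geno = raw.split(",", 1)
        name = name.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenePopParseError(
                f"expected {len(loci)} genotypes, found {len(tokens)}", i + 1
            )
        if width is None:
            if len(tokens[0]) not in (4, 6):
                raise GenePopParseError(
                    f"genotype token {tokens[0]!r} is neither 4 nor 6 digits", i + 1
                )
            width = len(tokens[0]) // 2
        if pop_label is None:
            stem = name.split("_")[0].split("-")[0]
            pop_label = stem if stem and not stem.isdigit() else f"pop{pop_index}"
        ids.append(name)
        pops.append(pop_label)
        rows.append([_parse_genepop_allele(t, width, i + 1) for t in tokens])
        i += 1
    if not rows:
        raise GenePopParseError("no individuals found", len(lines))
    calls = np.array(rows, dtype=np.int64)
    return GenotypeMatrix(ids, pops, loci, calls)


def write_genepop(g: GenotypeMatrix, path: str | Path, title: str = "fragdrift") -> None:
    """Write GenePop with 3-digit alleles (microsatellite sizes exceed 99 bp).

    GenePop has no population-name field, so the site code is encoded as a
    prefix of each individual name (``CODE_id``, the common convention);
    :func:`read_genepop` recovers it from that prefix.
    """
    if (g.calls > 999).any():
        raise ValueError("allele size exceeds 999; GenePop 3-digit dialect overflows")
    out = [title]
    out.extend(g.locus_names)
    last_pop = None
    for i in range(g.n_individuals):
        pop = g.pops[i]
        if pop != last_pop:
            out.append("Pop")
            last_pop = pop
        toks = []
        for j in range(g.n_loci):
            a, b = g.calls[i, j]
            toks.append(f"{max(a, 0):03d}{max(b, 0):03d}")
        name = g.ids[i] if g.ids[i].split("_")[0] == pop else f"{pop}_{g.ids[i]}"
        out.append(f"{name} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Delimited-table I/O


def write_genotype_table(g: GenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    g.to_dataframe().to_csv(path, sep=sep, index=False)


def read_genotype_table(path: str | Path, sep: str = "\t") -> GenotypeMatrix:
    df = pd.read_csv(path, sep=sep, dtype=str)
    loci = [c for c in df.columns if c not in ("id", "pop")]
    calls = np.full((len(df), len(loci), 2), MISSING, dtype=np.int64)
    for j, name in enumerate(loci):
        for i, cell in enumerate(df[name]):
            if isinstance(cell, str) and "/" in cell:
                a, b = cell.split("/")
                calls[i, j] = (int(a), int(b))
    return GenotypeMatrix(df["id"].tolist(), df["pop"].tolist(), loci, calls)


def read_site_table(path: str | Path, sep: str = "\t") -> list[SiteInfo]:
    """Read a site table with columns code, latitude, longitude[, census]."""
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    out = []
    for _, row in df.iterrows():
        out.append(
            SiteInfo(
                code=str(row["code"]),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                census=str(row.get("census", "")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Clone (identical multi-locus genotype) handling


def _pair_matches(a: np.ndarray, b: np.ndarray) -> bool:
    """Match under the permissive missing-data policy.

    Two individuals match iff every mutually scored locus carries the same
    unordered allele pair, with at least one mutually scored locus.
    """
    scored = (a[:, 0] != MISSING) & (b[:, 0] != MISSING)
    if not scored.any():
        return False
    return bool((a[scored] == b[scored]).all())


def find_clones(g: GenotypeMatrix) -> list[list[int]]:
    """Partition individual indices into groups of identical multi-locus genotypes.

    Identical genotypes in a clonal plant are interpreted as ramets (root
    suckers) of one genet.  Individuals are compared only at mutually
    non-missing loci; singletons are returned as groups of size one.
    Matching is transitive-closure over pairwise matches (missing data can
    make matching non-transitive; the union keeps the partition well defined).
    """
    n = g.n_individuals
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # hash complete genotypes first to avoid the O(n^2) loop in the common case
    complete = ~g.missing_mask().any(axis=1)
    buckets: dict[bytes, int] = {}
    for i in np.flatnonzero(complete):
        key = g.calls[i].tobytes()
        if key in buckets:
            parent[find(i)] = find(buckets[key])
        else:
            buckets[key] = i
    incomplete = np.flatnonzero(~complete)
    for i in incomplete:
        for j in range(g.n_individuals):
            if j == i:
                continue
            if _pair_matches(g.calls[i], g.calls[j]):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted((sorted(v) for v in groups.values()), key=lambda v: v[0])


def dedup_clones(g: GenotypeMatrix) -> GenotypeMatrix:
    """Keep the first-encountered member of every clone group.

    Downstream diversity and structure statistics assume random samples of
    distinct genets; retaining ramet duplicates would skew allele
    frequencies toward the cloned genotypes.
    """
    keep = sorted(grp[0] for grp in find_clones(g))
    return g.subset(keep)


# ---------------------------------------------------------------------------
# Allele frequencies


class AlleleFrequencyTable:
    """Per-population, per-locus allele frequencies and gene counts.

    Backed by a long-format :class:`pandas.DataFrame` with columns
    ``pop, locus, allele, count, freq`` plus a gene-count lookup.  A
    (pop, locus) cell with zero scored genes is recorded as *empty* rather
    than NaN-propagating.
    """

    def __init__(self, table: pd.DataFrame, genes: pd.DataFrame):
        self.table = table
        self.genes = genes  # columns pop, locus, genes

    def freqs(self, pop: str, locus: str) -> dict[int, float]:
        sel = self.table[(self.table["pop"] == pop) & (self.table["locus"] == locus)]
        return dict(zip(sel["allele"].astype(int), sel["freq"].astype(float)))

    def counts(self, pop: str, locus: str) -> dict[int, int]:
        sel = self.table[(self.table["pop"] == pop) & (self.table["locus"] == locus)]
        return dict(zip(sel["allele"].astype(int), sel["count"].astype(int)))

    def gene_count(self, pop: str, locus: str) -> int:
        sel = self.genes[(self.genes["pop"] == pop) & (self.genes["locus"] == locus)]
        return int(sel["genes"].iloc[0]) if len(sel) else 0

    def is_empty(self, pop: str, locus: str) -> bool:
        return self.gene_count(pop, locus) == 0

    def pooled_freqs(self, locus: str) -> dict[int, float]:
        """Frequencies over all populations pooled (gene-count weighted)."""
        sel = self.table[self.table["locus"] == locus]
        tot = sel["count"].sum()
        if tot == 0:
            return {}
        agg = sel.groupby("allele")["count"].sum()
        return {int(a): c / tot for a, c in agg.items()}


def allele_frequencies(g: GenotypeMatrix, by_population: bool = True) -> AlleleFrequencyTable:
    """Tally allele relative frequencies per (population, locus).

    Frequencies are over non-missing gene copies only and sum to one within
    each non-empty cell.
    """
    pops = g.populations if by_population else ["_all"]
    rows = []
    gene_rows = []
    for pop in pops:
        sub = g if pop == "_all" else g.by_population(pop)
        for j, name in enumerate(g.locus_names):
            alleles = sub.calls[:, j, :].ravel()
            alleles = alleles[alleles != MISSING]
            gene_rows.append({"pop": pop, "locus": name, "genes": alleles.size})
            if alleles.size == 0:
                continue
            vals, counts = np.unique(alleles, return_counts=True)
            for a, c in zip(vals, counts):
                rows.append(
                    {
                        "pop": pop,
                        "locus": name,
                        "allele": int(a),
                        "count": int(c),
                        "freq": c / alleles.size,
                    }
                )
    table = pd.DataFrame(rows, columns=["pop", "locus", "allele", "count", "freq"])
    genes = pd.DataFrame(gene_rows, columns=["pop", "locus", "genes"])
    return AlleleFrequencyTable(table, genes)
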