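"""Wright-Fisher genetic-drift simulation from observed or synthetic genotypes.

The simulated management question: how fast do small, isolated remnant
populations lose gene diversity and alleles?  The procedure mirrors the
classic resampling design:

1. found a panmictic pool (default 500 individuals) by random union of
   gametes drawn with replacement from a source genotype sample (t = 1);
2. for each of R replicates draw N individuals the same way and resample
   independently for T non-overlapping generations (t = 2 .. T), each
   generation formed by drawing two alleles per locus with replacement
   from the previous generation (free recombination, constant N);
3. record per generation the unbiased expected heterozygosity and the mean
   number of alleles over loci, with replicate-SD-based confidence bands.

Expected He decays as (1 - 1/2N)^(t-1), the module's analytic oracle; the
half-life utilities report the first generation at which the replicate
mean of a metric falls to half its founding (t = 1) value.  A one-shot
population-mixing operation models assisted migration: equal random draws
from several source populations concatenated into one founding sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "MixSpec",
    "SimulationTrajectory",
    "found_panmictic",
    "simulate_constant_n",
    "mix_populations",
    "half_life",
]


@dataclass(frozen=True)
class SimConfig:
    """Constant-N simulation settings.

    ``n`` is the constant (effective) population size per replicate;
    ``generations`` counts from the founding pool at t = 1, so T = 200
    runs 199 resampling events; ``ci`` is the confidence level for the
    replicate-SD band (mean +/- z * SD).
    """

    n: int
    generations: int = 200
    replicates: int = 100
    ci: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.generations < 1 or self.replicates < 1:
            raise ValueError("sizes, generations and replicates must be >= 1")
        if not 0.0 < self.ci < 1.0:
            raise ValueError("ci level must lie in (0, 1)")


@dataclass(frozen=True)
class MixSpec:
    """One-shot mixing: draw ``per_source`` individuals (without
    replacement) from each source population and concatenate."""

    per_source: int = 20
    seed: int = 0


@dataclass
class SimulationTrajectory:
    """Per-generation replicate trajectories of He and mean allele number.

    ``he`` and ``alleles`` have shape (T, R); row 0 is the founding pool
    (t = 1), identical across replicates.  ``summary()`` returns the
    replicate mean with the configured confidence band.
    """

    he: np.ndarray
    alleles: np.ndarray
    config: SimConfig

    @property
    def generations(self) -> np.ndarray:
        return np.arange(1, self.he.shape[0] + 1)

    def mean(self, metric: str = "he") -> np.ndarray:
        return self._metric(metric).mean(axis=1)

    def _metric(self, metric: str) -> np.ndarray:
        if metric in ("he", "He"):
            return self.he
        if metric in ("alleles", "A", "Ar"):
            return self.alleles
        raise ValueError(f"unknown metric {metric!r}")

    def summary(self, metric: str = "he") -> pd.DataFrame:
        vals = self._metric(metric)
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1) if vals.shape[1] > 1 else np.zeros_like(mean)
        z = _stats.norm.ppf(0.5 + self.config.ci / 2.0)
        return pd.DataFrame(
            {
                "generation": self.generations,
                "mean": mean,
                "ci_low": mean - z * sd,
                "ci_high": mean + z * sd,
            }
        )

    def to_long(self) -> pd.DataFrame:
        t, r = np.meshgrid(self.generations, np.arange(1, self.he.shape[1] + 1),
                           indexing="ij")
        return pd.DataFrame(
            {
                "generation": t.ravel(),
                "replicate": r.ravel(),
                "he": self.he.ravel(),
                "alleles": self.alleles.ravel(),
            }
        )


# ---------------------------------------------------------------------------


def _gene_pools(g: GenotypeMatrix) -> list[np.ndarray]:
    """Non-missing gene copies per locus (allele sizes)."""
    pools = []
    for j in range(g.n_loci):
        a = g.calls[:, j, :]
        a = a[a[:, 0] != MISSING].ravel()
        if a.size == 0:
            raise ValueError(f"locus {g.locus_names[j]!r} has no scored genes")
        pools.append(a)
    return pools


def found_panmictic(g: GenotypeMatrix, pool_size: int = 500, seed: int = 0) -> GenotypeMatrix:
    """Found a panmictic pool by random union of gametes.

    Each of ``pool_size`` individuals receives, at every locus, two alleles
    drawn with replacement from the source's allele pool, erasing family
    and HWE-departure structure while preserving allele frequencies in
    expectation.
    """
    if g.n_individuals == 0:
        raise ValueError("source matrix is empty")
    rng = np.random.default_rng(seed)
    pools = _gene_pools(g)
    calls = np.empty((pool_size, g.n_loci, 2), dtype=np.int64)
    for j, pool in enumerate(pools):
        calls[:, j, :] = rng.choice(pool, size=(pool_size, 2), replace=True)
    ids = [f"sim_{i + 1:04d}" for i in range(pool_size)]
    return GenotypeMatrix(ids, ["pool"] * pool_size, g.locus_names, calls)


def _diversity_stats(state: np.ndarray, ks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased He and allele count per replicate, averaged over loci.

    ``state``: (R, L, 2N) compact allele indices; ``ks``: alleles per locus.
    """
    R, L, genes = state.shape
    he = np.empty((R, L))
    counts = np.empty((R, L))
    for l in range(L):
        k = int(ks[l])
        offs = (np.arange(R) * k)[:, None]
        flat = (state[:, l, :] + offs).ravel()
        cnt = np.bincount(flat, minlength=R * k).reshape(R, k)
        p = cnt / genes
        sump2 = (p**2).sum(axis=1)
        he[:, l] = genes / (genes - 1.0) * (1.0 - sump2) if genes > 1 else 0.0
        counts[:, l] = (cnt > 0).sum(axis=1)
    return he.mean(axis=1), counts.mean(axis=1)


def simulate_constant_n(pool: GenotypeMatrix, config: SimConfig) -> SimulationTrajectory:
    """Replicated constant-N Wright-Fisher resampling from a founding pool.

    Row t = 1 of the trajectory is the pool itself; each replicate draws N
    individuals (two alleles with replacement per locus) from the pool for
    t = 2, then resamples itself for each later generation.  He is Nei's
    unbiased estimator on the N simulated individuals; the allele metric is
    the plain mean allele count over loci.
    """
    rng = np.random.default_rng(config.seed)
    pools = _gene_pools(pool)
    L = len(pools)
    R, N, T = config.replicates, config.n, config.generations
    genes = 2 * N

    # compact per-locus coding of the pool's gene copies
    coded_pools = []
    ks = np.empty(L, dtype=int)
    sizes_per_locus = []
    for p in pools:
        alleles = np.unique(p)
        coded_pools.append(np.searchsorted(alleles, p))
        sizes_per_locus.append(alleles)
        ks[len(coded_pools) - 1] = len(alleles)

    he = np.empty((T, R))
    al = np.empty((T, R))
    # t = 1: the founding pool itself (pool sizes may differ per locus
    # when the source carries missing data)
    he0 = al0 = 0.0
    for coded in coded_pools:
        cnt = np.bincount(coded)
        p = cnt / coded.size
        he0 += coded.size / (coded.size - 1.0) * (1.0 - float(p @ p))
        al0 += int((cnt > 0).sum())
    he[0, :] = he0 / L
    al[0, :] = al0 / L

    # initial replicate draw from the pool
    state = np.empty((R, L, genes), dtype=np.int64)
    for l, coded in enumerate(coded_pools):
        idx = rng.integers(0, coded.size, size=(R, genes))
        state[:, l, :] = coded[idx]
    if T >= 2:
        he[1], al[1] = _diversity_stats(state, ks)
    for t in range(2, T):
        idx = rng.integers(0, genes, size=(R, L, genes))
        state = np.take_along_axis(state, idx, axis=2)
        he[t], al[t] = _diversity_stats(state, ks)
    return SimulationTrajectory(he=he, alleles=al, config=config)


def mix_populations(
    sources: list[GenotypeMatrix], spec: MixSpec = MixSpec()
) -> GenotypeMatrix:
    """Concatenate equal random draws (without replacement) from each source.

    Models a one-shot assisted-migration mix; the result is used as the
    source for :func:`found_panmictic` and onward simulation.
    """
    if len(sources) < 2:
        raise ValueError("mixing requires at least two source populations")
    rng = np.random.default_rng(spec.seed)
    parts = []
    for s in sources:
        if spec.per_source > s.n_individuals:
            raise ValueError(
                f"draw of {spec.per_source} exceeds source size {s.n_individuals}"
            )
        idx = rng.choice(s.n_individuals, size=spec.per_source, replace=False)
        parts.append(s.subset(np.sort(idx)))
    return GenotypeMatrix.concat(parts)


def half_life(trajectory: SimulationTrajectory, metric: str = "he") -> int | None:
    """First generation at which the replicate-mean metric halves.

    The reference is the t = 1 (founding pool) value; returns ``None`` if
    the metric never reaches half within the simulated horizon.
    """
    mean = trajectory.mean(metric)
    target = mean[0] / 2.0
    hits = np.flatnonzero(mean <= target)
    return int(hits[0] + 1) if hits.size else None
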