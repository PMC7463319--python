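"""Heterozygosity-excess test for recent effective-population-size crashes.

After a recent bottleneck, rare alleles are lost faster than gene diversity,
so the observed expected heterozygosity at a locus exceeds the equilibrium
heterozygosity expected for the *observed* number of alleles.  The test:

1. for each polymorphic locus, simulate samples at mutation-drift
   equilibrium conditioned on the observed allele count k and sample size
   (gene copies), under one of three microsatellite mutation models —
   infinite alleles (IAM), strict stepwise (SMM) or two-phase (TPM);
2. standardise the observed heterozygosity against the simulated
   distribution, DH = (He_obs - mean Heq) / SD(Heq);
3. combine loci with a one-tailed Wilcoxon signed-rank test in the excess
   direction (chosen over the sign test because marker panels are small).

Conditioning uses the Cornuet-Luikart approach: the scaled mutation rate
theta is tuned so the expected allele count matches k, then replicates are
rejection-conditioned on exactly k alleles.  IAM samples come from Hoppe's
urn (the Ewens sampling distribution); SMM/TPM samples from a Kingman
coalescent with stepwise mutations placed on the branches.  A qualitative
mode-shift indicator of the pooled allele-frequency distribution is also
provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import bh_fdr, expected_het
from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "MutationModelSpec",
    "LocusBottleneckResult",
    "simulate_heq",
    "het_excess_test",
    "mode_shift",
]


@dataclass(frozen=True)
class MutationModelSpec:
    """Mutation model for equilibrium simulation.

    ``p_smm`` is the proportion of single-step mutations under the TPM;
    ``variance`` the variance of the multi-step geometric step size (the
    conventional "variance 30" parameterisation).  ``iterations`` is the
    number of accepted equilibrium replicates per locus.
    """

    model: str = "TPM"
    p_smm: float = 0.70
    variance: float = 30.0
    iterations: int = 1000

    def __post_init__(self) -> None:
        if self.model not in ("IAM", "SMM", "TPM"):
            raise ValueError("model must be one of IAM, SMM, TPM")
        if not 0.0 <= self.p_smm <= 1.0:
            raise ValueError("proportion of SMM must lie in [0, 1]")
        if self.variance <= 0:
            raise ValueError("TPM variance must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class LocusBottleneckResult:
    locus: str
    k: int
    genes: int
    he_obs: float
    heq_mean: float
    heq_sd: float
    dh: float


class ConditioningError(RuntimeError):
    """Raised when exactly-k conditioning fails within the rejection budget."""


# ---------------------------------------------------------------------------
# equilibrium samplers


def _ewens_expected_k(theta: float, n: int) -> float:
    i = np.arange(n, dtype=float)
    return float(np.sum(theta / (theta + i)))


def _crp_batch(rng: np.random.Generator, batch: int, n: int, theta: float):
    """Hoppe's urn / Chinese-restaurant sample of `batch` IAM genealogies.

    Returns (unbiased gene diversity, allele count) per replicate.
    """
    labels = np.zeros((batch, n), dtype=np.int64)
    rows = np.arange(batch)
    for i in range(1, n):
        new = rng.uniform(size=batch) < theta / (theta + i)
        copy_from = rng.integers(0, i, size=batch)
        labels[:, i] = np.where(new, i, labels[rows, copy_from])
    offs = (rows * n)[:, None]
    cnt = np.bincount((labels + offs).ravel(), minlength=batch * n).reshape(batch, n)
    p = cnt / n
    h = n / (n - 1.0) * (1.0 - (p**2).sum(axis=1))
    k = (cnt > 0).sum(axis=1)
    return h, k


def _geom_p_for_variance(variance: float) -> float:
    # step magnitude ~ Geometric on {1, 2, ...} with Var = (1-p)/p^2
    return (np.sqrt(1.0 + 4.0 * variance) - 1.0) / (2.0 * variance)


def _stepwise_sample(
    rng: np.random.Generator, n: int, theta: float, p_single: float, geom_p: float
) -> np.ndarray:
    """One coalescent sample of n genes with stepwise mutations.

    Returns allele states (repeat scores relative to the root).  With
    ``p_single = 1`` every mutation is +/-1 (SMM); otherwise a fraction is
    multi-step geometric (TPM).
    """
    values = np.zeros(n)
    active: list[np.ndarray] = [np.array([i]) for i in range(n)]
    while len(active) > 1:
        j = len(active)
        t = rng.exponential(2.0 / (j * (j - 1)))
        m = rng.poisson(theta * t / 2.0, size=j)
        for idx in np.flatnonzero(m):
            k = int(m[idx])
            signs = rng.choice((-1.0, 1.0), size=k)
            if p_single >= 1.0:
                sizes = np.ones(k)
            else:
                single = rng.uniform(size=k) < p_single
                sizes = np.where(single, 1.0, rng.geometric(geom_p, size=k))
            step = float(signs @ sizes)
            if step:
                values[active[idx]] += step
        a, b = rng.choice(j, size=2, replace=False)
        merged = np.concatenate([active[a], active[b]])
        active = [lin for i, lin in enumerate(active) if i not in (a, b)]
        active.append(merged)
    return values


def _stepwise_batch(rng, batch: int, n: int, theta: float, p_single: float, geom_p: float):
    h = np.empty(batch)
    k = np.empty(batch, dtype=int)
    for b in range(batch):
        vals = _stepwise_sample(rng, n, theta, p_single, geom_p)
        _, cnt = np.unique(vals, return_counts=True)
        p = cnt / n
        h[b] = n / (n - 1.0) * (1.0 - float(p @ p))
        k[b] = len(cnt)
    return h, k


def _tune_theta(
    rng: np.random.Generator, k: int, n: int, spec: MutationModelSpec
) -> float:
    """theta with expected allele count equal to k (bisection).

    Closed form for the IAM via the Ewens expectation; simulation-based
    bisection for the stepwise models.
    """
    if spec.model == "IAM":
        lo, hi = 1e-6, 1e6
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if _ewens_expected_k(mid, n) < k:
                lo = mid
            else:
                hi = mid
        return float(np.sqrt(lo * hi))
    geom_p = _geom_p_for_variance(spec.variance)
    p_single = 1.0 if spec.model == "SMM" else spec.p_smm
    lo, hi = 1e-3, 1e4
    for _ in range(18):
        mid = np.sqrt(lo * hi)
        _, ks = _stepwise_batch(rng, 250, n, mid, p_single, geom_p)
        if ks.mean() < k:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_heq(
    k: int,
    genes: int,
    spec: MutationModelSpec,
    seed: int | np.random.SeedSequence = 0,
    budget_factor: int = 100,
) -> np.ndarray:
    """Equilibrium gene diversities conditioned on exactly k alleles.

    Tunes theta so E[alleles] = k, then rejection-samples coalescent
    replicates until ``spec.iterations`` carry exactly k alleles in a
    sample of ``genes`` gene copies.  Raises :class:`ConditioningError`
    with diagnostics if the acceptance budget (``budget_factor`` times the
    requested iterations) is exhausted.
    """
    if not 2 <= k <= genes:
        raise ValueError("need 2 <= k <= genes")
    rng = np.random.default_rng(seed)
    theta = _tune_theta(rng, k, genes, spec)
    p_single = 1.0 if spec.model in ("SMM",) else spec.p_smm
    geom_p = _geom_p_for_variance(spec.variance)
    accepted: list[np.ndarray] = []
    n_acc = 0
    attempts = 0
    budget = budget_factor * spec.iterations
    batch = max(200, spec.iterations)
    while n_acc < spec.iterations:
        if attempts >= budget:
            raise ConditioningError(
                f"conditioning on k={k} (genes={genes}, {spec.model}) accepted "
                f"{n_acc}/{spec.iterations} after {attempts} attempts at "
                f"theta={theta:.4g}"
            )
        b = min(batch, budget - attempts)
        if spec.model == "IAM":
            h, ks = _crp_batch(rng, b, genes, theta)
        else:
            h, ks = _stepwise_batch(rng, b, genes, theta, p_single, geom_p)
        attempts += b
        hit = h[ks == k]
        if hit.size:
            accepted.append(hit)
            n_acc += hit.size
    return np.concatenate(accepted)[: spec.iterations]


# ---------------------------------------------------------------------------
# per-population test


def _locus_obs(g: GenotypeMatrix, pop: str) -> list[tuple[str, int, int, float]]:
    sub = g.by_population(pop)
    he = expected_het(sub)
    out = []
    for j, name in enumerate(g.locus_names):
        a = sub.calls[:, j, :]
        a = a[a[:, 0] != MISSING].ravel()
        k = len(np.unique(a)) if a.size else 0
        if k >= 2:
            out.append((name, k, int(a.size), float(he.loc[pop, name])))
    return out


def het_excess_test(
    g: GenotypeMatrix,
    spec: MutationModelSpec = MutationModelSpec(),
    seed: int = 0,
    fdr_q: float = 0.05,
    heq_cache: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, list[LocusBottleneckResult]]]:
    """One-tailed Wilcoxon heterozygosity-excess test per population.

    Per polymorphic locus the standardised deviation
    DH = (He_obs - mean Heq)/SD(Heq) is computed against the conditional
    equilibrium distribution; the signed deviations are combined with a
    one-tailed Wilcoxon signed-rank test in the excess direction.  FDR
    decisions across populations use Benjamini-Hochberg at ``fdr_q``.

    ``heq_cache`` may be supplied to reuse simulated (k, genes) equilibrium
    distributions across populations; entries are keyed by the full model
    configuration so different specs never collide.
    """
    cache = heq_cache if heq_cache is not None else {}
    rows = []
    details: dict[str, list[LocusBottleneckResult]] = {}
    for pop in g.populations:
        obs = _locus_obs(g, pop)
        if len(obs) < 4:
            warnings.warn(
                f"population {pop!r}: only {len(obs)} polymorphic loci; "
                "the signed-rank p-value is unreliable at this size"
            )
        dhs = []
        detail = []
        for name, k, genes, he_obs in obs:
            key = (k, genes, spec.model, spec.p_smm, spec.variance, spec.iterations)
            if key not in cache:
                ss = np.random.SeedSequence(seed, spawn_key=(k, genes))
                heq = simulate_heq(k, genes, spec, seed=ss)
                cache[key] = (
                    float(heq.mean()),
                    float(heq.std(ddof=1)),
                    float(np.median(heq)),
                )
            mu, sd, med = cache[key]
            dh = (he_obs - mu) / sd if sd > 0 else 0.0
            # the signed-rank statistic is centred at the simulated median:
            # the conditional Heq distribution is left-skewed, and centring
            # at the mean makes the one-tailed test anti-conservative
            dhs.append((he_obs - med) / sd if sd > 0 else 0.0)
            detail.append(LocusBottleneckResult(name, k, genes, he_obs, mu, sd, dh))
        details[pop] = detail
        dhs = np.asarray(dhs)
        if dhs.size == 0:
            p = np.nan
        elif np.allclose(dhs, 0.0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(dhs, alternative="greater").pvalue)
        rows.append({"pop": pop, "n_loci": len(obs), "p_excess": p})
    table = pd.DataFrame(rows).set_index("pop")
    ok = table["p_excess"].notna()
    table["significant_fdr"] = False
    if ok.any():
        reject, adj = bh_fdr(table.loc[ok, "p_excess"].to_numpy(), q=fdr_q)
        table.loc[ok, "significant_fdr"] = reject
        table.loc[ok, "p_adjusted"] = adj
    table["mode_shift"] = mode_shift(g)
    return table, details


def mode_shift(g: GenotypeMatrix) -> pd.Series:
    """Qualitative allele-frequency-distribution descriptor per population.

    Allele frequencies are pooled across loci into ten classes
    (0-0.1], ..., (0.9-1.0]; a population at mutation-drift equilibrium has
    an L-shaped distribution (the rarest class is modal).  Label is
    "L-shaped" when the lowest class holds at least as many alleles as any
    other class, else "shifted".
    """
    labels = {}
    for pop in g.populations:
        sub = g.by_population(pop)
        freqs = []
        for j in range(g.n_loci):
            a = sub.calls[:, j, :]
            a = a[a[:, 0] != MISSING].ravel()
            if a.size == 0:
                continue
            _, cnt = np.unique(a, return_counts=True)
            freqs.extend(cnt / a.size)
        if not freqs:
            labels[pop] = "undetermined"
            continue
        bins = np.ceil(np.asarray(freqs) * 10.0).astype(int) - 1
        bins = np.clip(bins, 0, 9)
        hist = np.bincount(bins, minlength=10)
        labels[pop] = "L-shaped" if hist[0] >= hist[1:].max() else "shifted"
    return pd.Series(labels, name="mode_shift")
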