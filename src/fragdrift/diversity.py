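"""Descriptive and structure statistics for codominant genotype data.

Implements the classical microsatellite summary toolkit: observed and
Nei-unbiased expected heterozygosity, hypergeometric rarefied allelic
richness, Weir & Cockerham (1984) variance-component F-statistics (global
theta with a bootstrap-over-loci CI, per-population FIS), permutation tests
for pairwise FST, Brookfield's formula-1 null-allele frequency,
isolation-by-distance (Slatkin-linearised FST against log geographic
distance, Mantel + regression), and Benjamini-Hochberg FDR control.

Estimator conventions
---------------------
* Expected heterozygosity is Nei's unbiased gene diversity
  ``(2n/(2n-1)) * (1 - sum p^2)`` with ``n`` the number of scored diploids.
* Negative theta estimates are reported as computed, not truncated.
* Permutation p-values use the add-one rule ``(hits + 1)/(B + 1)``.
* All statistics are computed on locus-wise available (non-missing) data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .genotypes import MISSING, GenotypeMatrix, allele_frequencies

__all__ = [
    "DiversitySummary",
    "FstResult",
    "observed_het",
    "expected_het",
    "allelic_richness",
    "wc_fstatistics",
    "pairwise_fst",
    "brookfield_null_freq",
    "ibd_test",
    "bh_fdr",
    "diversity_summary",
    "haversine_km",
]


# ---------------------------------------------------------------------------
# locus coding helpers


def _locus_codes(g: GenotypeMatrix) -> list[tuple[np.ndarray, int]]:
    """Per locus: calls recoded to compact allele indices (missing -> -1)."""
    out = []
    for j in range(g.n_loci):
        raw = g.calls[:, j, :]
        alleles = np.unique(raw[raw != MISSING])
        codes = np.searchsorted(alleles, raw)
        codes[raw == MISSING] = -1
        out.append((codes, len(alleles)))
    return out


def _pop_indices(g: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    pops = g.populations
    lookup = {p: i for i, p in enumerate(pops)}
    return np.array([lookup[p] for p in g.pops]), pops


# ---------------------------------------------------------------------------
# heterozygosities


def observed_het(g: GenotypeMatrix) -> pd.DataFrame:
    """Observed heterozygosity per population: per-locus columns plus a
    ``mean`` column over loci with data (loci without data are excluded)."""
    rows = {}
    for pop in g.populations:
        sub = g.by_population(pop)
        scored = ~sub.missing_mask()
        het = (sub.calls[:, :, 0] != sub.calls[:, :, 1]) & scored
        n = scored.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = np.where(n > 0, het.sum(axis=0) / n, np.nan)
        rows[pop] = ho
    df = pd.DataFrame(rows, index=g.locus_names).T
    df["mean"] = df[g.locus_names].mean(axis=1, skipna=True)
    return df


def expected_het(g: GenotypeMatrix) -> pd.DataFrame:
    """Nei's unbiased expected heterozygosity per population and locus.

    He = (2n/(2n-1)) * (1 - sum p^2); a (pop, locus) cell with fewer than
    two scored gene copies is excluded (NaN).
    """
    rows = {}
    for pop in g.populations:
        sub = g.by_population(pop)
        vals = np.full(g.n_loci, np.nan)
        for j in range(g.n_loci):
            a = sub.calls[:, j, :]
            a = a[a[:, 0] != MISSING]
            genes = 2 * len(a)
            if genes < 2:
                continue
            _, counts = np.unique(a.ravel(), return_counts=True)
            p = counts / genes
            vals[j] = genes / (genes - 1.0) * (1.0 - float(p @ p))
        rows[pop] = vals
    df = pd.DataFrame(rows, index=g.locus_names).T
    df["mean"] = df[g.locus_names].mean(axis=1, skipna=True)
    return df


def allelic_richness(g: GenotypeMatrix, rarefaction_genes: int | None = None) -> pd.DataFrame:
    """Rarefied allelic richness per population (hypergeometric rarefaction).

    r = sum_alleles [1 - C(2n - N_i, G) / C(2n, G)]: the expected number of
    distinct alleles in a subsample of G gene copies.  By default G is, per
    locus, twice the smallest per-population sample with data (the FSTAT
    convention), so values are comparable across unequal samples; a fixed G
    may be supplied instead.
    """
    pops = g.populations
    counts: dict[tuple[str, int], np.ndarray] = {}
    genes = np.zeros((len(pops), g.n_loci), dtype=int)
    for pi, pop in enumerate(pops):
        sub = g.by_population(pop)
        for j in range(g.n_loci):
            a = sub.calls[:, j, :]
            a = a[a[:, 0] != MISSING].ravel()
            genes[pi, j] = a.size
            if a.size:
                counts[(pop, j)] = np.unique(a, return_counts=True)[1]

    result = {}
    for pi, pop in enumerate(pops):
        vals = np.full(g.n_loci, np.nan)
        for j in range(g.n_loci):
            gj = genes[:, j]
            G = rarefaction_genes if rarefaction_genes is not None else int(gj[gj > 0].min())
            tot = genes[pi, j]
            if tot == 0:
                continue
            if G > tot:
                raise ValueError(
                    f"rarefaction size {G} exceeds the {tot} gene copies of "
                    f"population {pop!r} at locus {g.locus_names[j]!r}"
                )
            ni = counts[(pop, j)]
            # log-space hypergeometric tail: C(tot - ni, G)/C(tot, G)
            with np.errstate(divide="ignore"):
                log_miss = (
                    special.gammaln(tot - ni + 1)
                    - special.gammaln(tot - ni - G + 1)
                    - special.gammaln(tot + 1)
                    + special.gammaln(tot - G + 1)
                )
            miss = np.where(tot - ni >= G, np.exp(log_miss), 0.0)
            vals[j] = float(np.sum(1.0 - miss))
        result[pop] = vals
    df = pd.DataFrame(result, index=g.locus_names).T
    df["mean"] = df[g.locus_names].mean(axis=1, skipna=True)
    return df


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components


def _wc_sums(
    codes_list: list[tuple[np.ndarray, int]],
    pop_idx: np.ndarray,
    n_pops: int,
    per_locus: bool = False,
):
    """Summed variance components (a, b, c) over alleles (and loci).

    Follows Weir & Cockerham (1984): per allele, among-population (a),
    among-individual-within-population (b) and within-individual (c)
    components, using sample sizes per population at each locus.
    """
    A = B = C = 0.0
    locus_rows = []
    for codes, k in codes_list:
        scored = codes[:, 0] >= 0
        if k < 2 or not scored.any():
            locus_rows.append((np.nan, np.nan, np.nan))
            continue
        pi = pop_idx[scored]
        cc = codes[scored]
        n_i = np.bincount(pi, minlength=n_pops).astype(float)
        keep = n_i > 0
        if keep.sum() < 2:
            locus_rows.append((np.nan, np.nan, np.nan))
            continue
        # allele counts per pop, heterozygote-carrier counts per pop
        cnt = np.zeros((n_pops, k))
        np.add.at(cnt, (pi, cc[:, 0]), 1.0)
        np.add.at(cnt, (pi, cc[:, 1]), 1.0)
        het = cc[:, 0] != cc[:, 1]
        hcnt = np.zeros((n_pops, k))
        np.add.at(hcnt, (pi[het], cc[het, 0]), 1.0)
        np.add.at(hcnt, (pi[het], cc[het, 1]), 1.0)

        n_i = n_i[keep]
        cnt = cnt[keep]
        hcnt = hcnt[keep]
        r = len(n_i)
        nbar = n_i.mean()
        nsum = r * nbar
        nc = (nsum - (n_i**2).sum() / nsum) / (r - 1)
        p = cnt / (2.0 * n_i[:, None])
        h = hcnt / n_i[:, None]
        pbar = (n_i[:, None] * p).sum(axis=0) / nsum
        s2 = (n_i[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i[:, None] * h).sum(axis=0) / nsum

        pq = pbar * (1.0 - pbar)
        a = (nbar / nc) * (s2 - (pq - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        la, lb, lc = float(a.sum()), float(b.sum()), float(c.sum())
        A += la
        B += lb
        C += lc
        locus_rows.append((la, lb, lc))
    if per_locus:
        return A, B, C, locus_rows
    return A, B, C


@dataclass
class FstResult:
    """Global Weir-Cockerham theta with per-locus components and CI."""

    theta: float
    per_locus: pd.DataFrame  # columns a, b, c, theta per locus
    ci_low: float
    ci_high: float
    fis: float  # global WC small-f over loci
    fis_per_pop: pd.Series  # 1 - Ho/He per population (summed over loci)
    p_value: float | None = None


@dataclass
class DiversitySummary:
    """Per-population summary table in the conventional column layout:
    n, mean alleles A, rarefied richness r, He, Ho, FIS."""

    table: pd.DataFrame


def wc_fstatistics(
    g: GenotypeMatrix,
    n_bootstrap: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> FstResult:
    """Weir & Cockerham (1984) theta (FST) and FIS.

    theta = sum(a) / sum(a + b + c) over alleles and loci; the confidence
    interval is a percentile bootstrap over loci.  With a single polymorphic
    locus the CI is degenerate (equal to the point estimate) and a warning
    is issued.  Per-population FIS is 1 - Ho/He with components summed over
    loci (He unbiased), the convention of standard summary tables.
    """
    pop_idx, pops = _pop_indices(g)
    if len(pops) < 2:
        raise ValueError("theta requires at least two populations")
    codes_list = _locus_codes(g)
    A, B, C, locus_rows = _wc_sums(codes_list, pop_idx, len(pops), per_locus=True)
    per_locus = pd.DataFrame(locus_rows, index=g.locus_names, columns=["a", "b", "c"])
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus["theta"] = per_locus["a"] / (
            per_locus["a"] + per_locus["b"] + per_locus["c"]
        )
    denom = A + B + C
    theta = A / denom if denom != 0 else np.nan
    fis = 1.0 - C / (B + C) if (B + C) != 0 else np.nan

    usable = per_locus.dropna()
    rng = np.random.default_rng(seed)
    if len(usable) < 2:
        warnings.warn("single polymorphic locus: bootstrap CI is degenerate")
        lo = hi = theta
    else:
        arr = usable[["a", "b", "c"]].to_numpy()
        idx = rng.integers(0, len(arr), size=(n_bootstrap, len(arr)))
        sums = arr[idx].sum(axis=1)  # (n_bootstrap, 3)
        with np.errstate(invalid="ignore", divide="ignore"):
            boot = sums[:, 0] / sums.sum(axis=1)
        alpha = (1.0 - ci) / 2.0
        lo, hi = np.nanquantile(boot, [alpha, 1.0 - alpha])

    ho = observed_het(g)["mean"]
    he = expected_het(g)["mean"]
    fis_pop = 1.0 - ho / he
    fis_pop.name = "fis"
    return FstResult(float(theta), per_locus, float(lo), float(hi), float(fis), fis_pop)


def _theta_only(codes_list, pop_idx, n_pops) -> float:
    A, B, C = _wc_sums(codes_list, pop_idx, n_pops)
    denom = A + B + C
    return A / denom if denom != 0 else np.nan


def pairwise_fst(
    g: GenotypeMatrix,
    permutations: int = 10000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise theta with label-permutation p-values.

    For each population pair the individuals' labels are permuted; the
    p-value is (number of permuted theta >= observed + 1) / (B + 1), the
    add-one-smoothed upper tail.  Returns (theta matrix, p matrix).
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    pop_idx, pops = _pop_indices(g)
    npop = len(pops)
    rng = np.random.default_rng(seed)
    theta_m = pd.DataFrame(np.nan, index=pops, columns=pops)
    p_m = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i in range(npop):
        for j in range(i + 1, npop):
            sel = np.flatnonzero((pop_idx == i) | (pop_idx == j))
            sub = g.subset(sel)
            sub_idx = (np.asarray(sub.pops) == pops[j]).astype(int)
            codes_list = _locus_codes(sub)
            obs = _theta_only(codes_list, sub_idx, 2)
            hits = 0
            labels = sub_idx.copy()
            for _ in range(permutations):
                rng.shuffle(labels)
                t = _theta_only(codes_list, labels, 2)
                if not np.isnan(t) and t >= obs:
                    hits += 1
            p = (hits + 1) / (permutations + 1)
            theta_m.iloc[i, j] = theta_m.iloc[j, i] = obs
            p_m.iloc[i, j] = p_m.iloc[j, i] = p
    return theta_m, p_m


# ---------------------------------------------------------------------------
# null alleles, IBD, FDR


def brookfield_null_freq(he, ho):
    """Brookfield's formula-1 null-allele frequency (He - Ho)/(1 + He).

    Appropriate when null homozygotes are not observed as blanks; a
    heterozygote excess (Ho > He) gives no null signal, so the estimate is
    floored at zero.  Accepts scalars or arrays.
    """
    he = np.asarray(he, dtype=float)
    ho = np.asarray(ho, dtype=float)
    if np.any((he < 0) | (he > 1)) or np.any((ho < 0) | (ho > 1)):
        raise ValueError("heterozygosities must lie in [0, 1]")
    out = np.maximum((he - ho) / (1.0 + he), 0.0)
    return float(out) if out.ndim == 0 else out


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a 6371-km sphere."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(h))


def _mantel(x: np.ndarray, y: np.ndarray, permutations: int, rng) -> tuple[float, float]:
    """Mantel correlation with joint row/column permutation of one matrix.

    Hand-rolled rather than delegated because Slatkin-linearised FST
    matrices routinely contain small negative entries (negative theta
    estimates are reported as computed), which strict distance-matrix
    containers reject.
    """
    n = x.shape[0]
    iu = np.triu_indices(n, 1)
    xv = x[iu]

    def corr(m):
        yv = m[iu]
        xs = xv - xv.mean()
        ys = yv - yv.mean()
        denom = np.sqrt((xs @ xs) * (ys @ ys))
        return xs @ ys / denom if denom > 0 else np.nan

    obs = corr(y)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if not np.isnan(r := corr(y[np.ix_(perm, perm)])) and abs(r) >= abs(obs):
            hits += 1
    return obs, (hits + 1) / (permutations + 1)


@dataclass
class IbdResult:
    slope: float
    intercept: float
    r_squared: float
    regression_p: float
    mantel_r: float
    mantel_p: float
    n_pairs: int


def ibd_test(
    fst_matrix: pd.DataFrame,
    sites,
    permutations: int = 10000,
    seed: int = 0,
) -> IbdResult:
    """Isolation by distance: linearised FST against log geographic distance.

    Pairwise theta is transformed to theta/(1 - theta) and regressed on the
    natural log of great-circle distance between sites; significance comes
    from both the regression and a two-sided Mantel permutation test
    (rows/columns of the genetic matrix permuted jointly).  Pairs with
    theta = 1 (linearisation undefined) are excluded with a warning.
    """
    site_map = {s.code: s for s in sites}
    codes = [c for c in fst_matrix.index if c in site_map]
    if len(codes) < 3:
        raise ValueError("isolation by distance requires at least three sites")
    theta = fst_matrix.loc[codes, codes].to_numpy(dtype=float)
    if np.any(theta[~np.isnan(theta)] >= 1.0):
        warnings.warn("theta = 1 pairs excluded: linearisation undefined")
    lat = np.array([site_map[c].latitude for c in codes])
    lon = np.array([site_map[c].longitude for c in codes])
    dist = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(dist, np.nan)
    if np.nanmin(dist) <= 0:
        raise ValueError("coincident sites: log-distance undefined")

    iu = np.triu_indices(len(codes), 1)
    lin = theta / (1.0 - theta)
    ok = np.isfinite(lin[iu]) & (theta[iu] < 1.0)
    x = np.log(dist[iu][ok])
    y = lin[iu][ok]
    reg = stats.linregress(x, y)

    logdist = np.log(dist)
    np.fill_diagonal(logdist, 0.0)
    lin_m = np.where(np.isfinite(lin), lin, 0.0)
    np.fill_diagonal(lin_m, 0.0)
    rng = np.random.default_rng(seed)
    mr, mp = _mantel(logdist, lin_m, permutations, rng)
    return IbdResult(
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
        regression_p=float(reg.pvalue),
        mantel_r=float(mr),
        mantel_p=float(mp),
        n_pairs=int(ok.sum()),
    )


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up control of the false discovery rate.

    Returns (reject, adjusted p-values) at level ``q``.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adj


# ---------------------------------------------------------------------------
# convenience summary


def diversity_summary(g: GenotypeMatrix, rarefaction_genes: int | None = None) -> DiversitySummary:
    """Per-population table: n, mean alleles A, rarefied r, He, Ho, FIS."""
    pops = g.populations
    freq = allele_frequencies(g)
    n = pd.Series({p: int((g.pops == p).sum()) for p in pops})
    a_mean = pd.Series(
        {
            p: np.mean(
                [
                    len(freq.freqs(p, loc))
                    for loc in g.locus_names
                    if not freq.is_empty(p, loc)
                ]
            )
            for p in pops
        }
    )
    rich = allelic_richness(g, rarefaction_genes)["mean"]
    he = expected_het(g)["mean"]
    ho = observed_het(g)["mean"]
    fis = 1.0 - ho / he
    table = pd.DataFrame(
        {"n": n, "A": a_mean, "r": rich, "He": he, "Ho": ho, "Fis": fis}
    ).loc[pops]
    return DiversitySummary(table)
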