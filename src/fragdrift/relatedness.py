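"""Pairwise relatedness, maximum-likelihood relationship classification and
spatial genetic autocorrelation.

Relatedness estimators implemented: Queller & Goodnight's regression
estimator, Lynch & Ritland's weighted regression estimator and Loiselle's
kinship coefficient (kinship is approximately r/2 for non-inbred pairs).
Relationship classification follows the maximum-likelihood approach over
the four standard pedigree hypotheses (unrelated, half-sib, full-sib,
parent-offspring), each a mixture over IBD modes with weights (k0, k1, k2).

Spatial structure is assessed two ways, matching field practice for plant
populations sampled at mapped coordinates:

* a multivariate autocorrelogram built from pairwise squared genetic
  distances (Smouse-Peakall construction) over "equal sample size"
  distance classes, with permutation null envelopes, and
* per-distance-class mean relatedness with permutation deviation tests and
  the standard class diagnostics (>100 pairs, participation > 50%,
  coefficient of variation of participation < 1).

Both permutation nulls shuffle whole individuals' coordinates, preserving
genotypic composition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "PairRelatedness",
    "Autocorrelogram",
    "reference_frequencies",
    "qg_relatedness",
    "lr_relatedness",
    "loiselle_kinship",
    "relatedness_matrix",
    "ml_relationship",
    "site_relatedness_summary",
    "spatial_autocorrelogram",
    "class_relatedness_profile",
]

RELATIONSHIPS: dict[str, tuple[float, float, float]] = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}


@dataclass(frozen=True)
class PairRelatedness:
    id1: str
    id2: str
    estimator: str
    r: float
    label: str | None = None


# ---------------------------------------------------------------------------
# reference frequencies


def reference_frequencies(g: GenotypeMatrix) -> list[tuple[dict[int, float], int]]:
    """Per-locus allele frequencies over the full analysed sample.

    Returns, per locus, a dict allele -> frequency and the number of scored
    gene copies.  The reference includes all individuals (no leave-out).
    """
    out = []
    for j in range(g.n_loci):
        a = g.calls[:, j, :]
        a = a[a[:, 0] != MISSING].ravel()
        if a.size == 0:
            out.append(({}, 0))
            continue
        vals, counts = np.unique(a, return_counts=True)
        out.append(({int(v): c / a.size for v, c in zip(vals, counts)}, int(a.size)))
    return out


def _freq(ref_l: dict[int, float], n_genes: int, allele: int) -> float:
    p = ref_l.get(allele)
    if p is None:
        warnings.warn(
            f"allele {allele} absent from reference table; using minimal frequency"
        )
        p = 1.0 / (n_genes + 1)
    return p


# ---------------------------------------------------------------------------
# pairwise estimators (single pair)


def _pair_calls(g: GenotypeMatrix, pair: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    i, j = pair
    return g.calls[i], g.calls[j]


def qg_relatedness(g: GenotypeMatrix, pair: tuple[int, int], ref=None) -> float:
    """Symmetrised Queller-Goodnight relatedness for one pair.

    Numerators and denominators are summed across loci before the ratio is
    taken, and the two directional forms are averaged.  Loci monomorphic in
    the reference, or missing in either individual, are skipped.
    """
    ref = ref if ref is not None else reference_frequencies(g)
    x, y = _pair_calls(g, pair)
    num_xy = den_xy = num_yx = den_yx = 0.0
    for l, (rl, ng) in enumerate(ref):
        if len(rl) < 2 or x[l, 0] == MISSING or y[l, 0] == MISSING:
            continue
        a, b = x[l]
        c, d = y[l]
        pa, pb = _freq(rl, ng, a), _freq(rl, ng, b)
        pc, pd_ = _freq(rl, ng, c), _freq(rl, ng, d)
        share = sum(int(u == v) for u in (a, b) for v in (c, d))
        num_xy += 0.5 * share - pa - pb
        den_xy += 1.0 + int(a == b) - pa - pb
        num_yx += 0.5 * share - pc - pd_
        den_yx += 1.0 + int(c == d) - pc - pd_
    parts = [n / d for n, d in ((num_xy, den_xy), (num_yx, den_yx)) if d != 0.0]
    return float(np.mean(parts)) if parts else np.nan


def lr_relatedness(g: GenotypeMatrix, pair: tuple[int, int], ref=None) -> float:
    """Symmetrised Lynch-Ritland relatedness with the published locus weights."""
    ref = ref if ref is not None else reference_frequencies(g)
    x, y = _pair_calls(g, pair)

    def directional(u: np.ndarray, v: np.ndarray) -> float:
        num = wsum = 0.0
        for l, (rl, ng) in enumerate(ref):
            if len(rl) < 2 or u[l, 0] == MISSING or v[l, 0] == MISSING:
                continue
            a, b = u[l]
            pa, pb = _freq(rl, ng, a), _freq(rl, ng, b)
            dv_a = sum(int(a == w) for w in v[l])
            dv_b = sum(int(b == w) for w in v[l])
            prod = pa * pb
            s = pa + pb if a != b else 2.0 * pa
            h = int(a == b)
            num += (pa * dv_b + pb * dv_a - 4.0 * prod) / (2.0 * prod)
            wsum += ((1.0 + h) * s - 4.0 * prod) / (2.0 * prod)
        return num / wsum if wsum != 0.0 else np.nan

    parts = [r for r in (directional(x, y), directional(y, x)) if np.isfinite(r)]
    return float(np.mean(parts)) if parts else np.nan


def loiselle_kinship(g: GenotypeMatrix, pair: tuple[int, int], ref=None) -> float:
    """Loiselle kinship coefficient (expected ~ r/2 for non-inbred pairs).

    f = [sum_l sum_a (x_a - p_a)(y_a - p_a) + p_a(1-p_a)/(n_l - 1)] /
        [sum_l sum_a p_a (1 - p_a)],
    with x_a the half-dosage of allele a in the individual and n_l the
    reference gene-copy count at locus l.
    """
    ref = ref if ref is not None else reference_frequencies(g)
    x, y = _pair_calls(g, pair)
    num = den = 0.0
    for l, (rl, ng) in enumerate(ref):
        if len(rl) < 2 or x[l, 0] == MISSING or y[l, 0] == MISSING:
            continue
        for allele, p in rl.items():
            xa = sum(int(allele == w) for w in x[l]) / 2.0
            ya = sum(int(allele == w) for w in y[l]) / 2.0
            num += (xa - p) * (ya - p) + p * (1.0 - p) / (ng - 1.0)
            den += p * (1.0 - p)
    return num / den if den > 0 else np.nan


# ---------------------------------------------------------------------------
# vectorised all-pairs matrices (complete-data fast path)


def _dosage_blocks(g: GenotypeMatrix):
    """Per locus: (dosage matrix (n, k), frequency vector, hom indicator)."""
    blocks = []
    for j in range(g.n_loci):
        raw = g.calls[:, j, :]
        alleles = np.unique(raw[raw != MISSING])
        if len(alleles) < 2:
            continue
        codes = np.searchsorted(alleles, raw)
        dos = np.zeros((g.n_individuals, len(alleles)))
        scored = raw[:, 0] != MISSING
        rows = np.flatnonzero(scored)
        np.add.at(dos, (rows, codes[scored, 0]), 1.0)
        np.add.at(dos, (rows, codes[scored, 1]), 1.0)
        p = dos.sum(axis=0)
        p = p / p.sum()
        hom = scored & (raw[:, 0] == raw[:, 1])
        blocks.append((dos, p, hom.astype(float), scored))
    return blocks


def relatedness_matrix(g: GenotypeMatrix, estimator: str = "qg") -> np.ndarray:
    """Full symmetric matrix of pairwise relatedness (or kinship).

    Vectorised over all pairs; requires complete data (falls back to the
    per-pair functions when genotypes are missing).  ``estimator`` is one
    of ``"qg"``, ``"lr"``, ``"loiselle"``.
    """
    n = g.n_individuals
    if g.missing_mask().any():
        ref = reference_frequencies(g)
        fn = {"qg": qg_relatedness, "lr": lr_relatedness, "loiselle": loiselle_kinship}[
            estimator
        ]
        m = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = fn(g, (i, j), ref)
        return m

    blocks = _dosage_blocks(g)
    if estimator == "qg":
        NUM = np.zeros((n, n))
        DEN = np.zeros(n)
        for dos, p, hom, _ in blocks:
            s = dos @ p
            NUM += 0.5 * (dos @ dos.T) - s[:, None]
            DEN += 1.0 + hom - s
        with np.errstate(invalid="ignore", divide="ignore"):
            R1 = NUM / DEN[:, None]
        out = 0.5 * (R1 + R1.T)
    elif estimator == "lr":
        NUMW = np.zeros((n, n))
        WSUM = np.zeros(n)
        for dos, p, hom, _ in blocks:
            q = dos / (2.0 * p)
            NUMW += q @ dos.T - 2.0
            s = dos @ p
            # product of the two allele frequencies of each genotype
            code = np.argsort(-dos, axis=1)[:, :2]
            pa = p[code[:, 0]]
            second = np.where(hom > 0, code[:, 0], code[:, 1])
            pb = p[second]
            prod = pa * pb
            WSUM += ((1.0 + hom) * s - 4.0 * prod) / (2.0 * prod)
        with np.errstate(invalid="ignore", divide="ignore"):
            R1 = NUMW / WSUM[:, None]
        out = 0.5 * (R1 + R1.T)
    elif estimator == "loiselle":
        num = np.zeros((n, n))
        den = 0.0
        for dos, p, hom, _ in blocks:
            ng = int(round(dos.sum()))
            z = dos / 2.0 - p
            num += z @ z.T + np.sum(p * (1 - p)) / (ng - 1.0)
            den += float(np.sum(p * (1.0 - p)))
        out = num / den
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    np.fill_diagonal(out, np.nan)
    return out


# ---------------------------------------------------------------------------
# maximum-likelihood relationship classification


def _genotype_prob(a: int, b: int, pa: float, pb: float) -> float:
    return pa * pa if a == b else 2.0 * pa * pb


def _transition(a, b, c, d, rl, ng) -> float:
    """P(second genotype | first, exactly one allele IBD between the pair)."""
    pc, pd_ = _freq(rl, ng, c), _freq(rl, ng, d)
    if a == b:
        if c == d:
            return pc if c == a else 0.0
        if a in (c, d):
            return pd_ if c == a else pc
        return 0.0
    # first is heterozygous a/b
    if c == d:
        if c == a or c == b:
            return pc / 2.0
        return 0.0
    if {c, d} == {a, b}:
        return (pc + pd_) / 2.0
    if c in (a, b):
        return pd_ / 2.0
    if d in (a, b):
        return pc / 2.0
    return 0.0


def ml_relationship(
    g: GenotypeMatrix, pair: tuple[int, int], ref=None
) -> tuple[str, dict[str, float]]:
    """Classify a pair into {U, HS, FS, PO} by maximum likelihood.

    The per-locus likelihood under a hypothesis with IBD-mode weights
    (k0, k1, k2) is k0*P(gx)P(gy) + k1*P(gx)T(gy|gx) + k2*P(gx)[gx = gy];
    the total is the product over loci.  Ties break toward the less related
    hypothesis (U before HS before FS before PO).  Returns the label and
    log-likelihood per hypothesis.
    """
    ref = ref if ref is not None else reference_frequencies(g)
    x, y = _pair_calls(g, pair)
    logl = {name: 0.0 for name in RELATIONSHIPS}
    for l, (rl, ng) in enumerate(ref):
        if len(rl) < 2 or x[l, 0] == MISSING or y[l, 0] == MISSING:
            continue
        a, b = int(x[l, 0]), int(x[l, 1])
        c, d = int(y[l, 0]), int(y[l, 1])
        pa, pb = _freq(rl, ng, a), _freq(rl, ng, b)
        pgx = _genotype_prob(a, b, pa, pb)
        pgy = _genotype_prob(c, d, _freq(rl, ng, c), _freq(rl, ng, d))
        l0 = pgx * pgy
        l1 = pgx * _transition(a, b, c, d, rl, ng)
        l2 = pgx if (a, b) == (c, d) else 0.0
        for name, (k0, k1, k2) in RELATIONSHIPS.items():
            lik = k0 * l0 + k1 * l1 + k2 * l2
            logl[name] += np.log(lik) if lik > 0 else -np.inf
    best = max(logl.values())
    for name in ("U", "HS", "FS", "PO"):  # less-related wins ties
        if logl[name] >= best - 1e-9:
            return name, logl
    return "U", logl  # pragma: no cover


def site_relatedness_summary(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-population percentages of U/HS/FS/PO among all within-site pairs.

    Percentages sum to 100; the ``related`` column is 100 minus the
    unrelated percentage.  Populations with fewer than two individuals give
    an empty (NaN) row.
    """
    rows = {}
    for pop in g.populations:
        sub = g.by_population(pop)
        n = sub.n_individuals
        if n < 2:
            rows[pop] = {k: np.nan for k in ("U", "HS", "FS", "PO", "related")}
            continue
        ref = reference_frequencies(sub)
        counts = {k: 0 for k in RELATIONSHIPS}
        pairs = list(itertools.combinations(range(n), 2))
        for pair in pairs:
            label, _ = ml_relationship(sub, pair, ref)
            counts[label] += 1
        pct = {k: 100.0 * v / len(pairs) for k, v in counts.items()}
        pct["related"] = 100.0 - pct["U"]
        rows[pop] = pct
    return pd.DataFrame(rows).T[["U", "HS", "FS", "PO", "related"]]


# ---------------------------------------------------------------------------
# spatial autocorrelation


def _genetic_sq_distance(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise squared genetic distance for codominant loci.

    Half the squared Euclidean distance between allele-dosage vectors,
    summed over loci, which reproduces the conventional codominant values
    (identical 0; AA-AB 1; AB-AC 1; AB-CD 2; AA-BC 3; AA-BB 4).  Missing
    genotypes are imputed at the locus mean dosage.
    """
    n = g.n_individuals
    parts = []
    for j in range(g.n_loci):
        raw = g.calls[:, j, :]
        alleles = np.unique(raw[raw != MISSING])
        if len(alleles) == 0:
            continue
        codes = np.searchsorted(alleles, raw)
        dos = np.zeros((n, len(alleles)))
        scored = raw[:, 0] != MISSING
        rows = np.flatnonzero(scored)
        np.add.at(dos, (rows, codes[scored, 0]), 1.0)
        np.add.at(dos, (rows, codes[scored, 1]), 1.0)
        if (~scored).any():
            dos[~scored] = dos[scored].mean(axis=0)
        parts.append(dos)
    dosage = np.hstack(parts)
    sq = np.sum(dosage**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * dosage @ dosage.T
    return 0.5 * np.maximum(d2, 0.0)


def _centered_covariance(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _equal_count_classes(
    dist: np.ndarray, n_classes: int
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Assign pair distances to classes of (near-)equal pair counts.

    Ties are kept together; exact-zero distances (co-located samples) form
    their own leading class when present.
    """
    labels = np.full(dist.shape, -1, dtype=int)
    classes: list[tuple[float, float]] = []
    nonzero = dist > 0
    offset = 0
    if (~nonzero).any():
        labels[~nonzero] = 0
        classes.append((0.0, 0.0))
        offset = 1
    vals = np.sort(dist[nonzero])
    if vals.size:
        edges = np.quantile(vals, np.linspace(0, 1, n_classes + 1))
        edges[0], edges[-1] = 0.0, np.inf
        edges = np.unique(edges)
        cls = np.searchsorted(edges, dist[nonzero], side="left") - 1
        cls = np.clip(cls, 0, len(edges) - 2)
        labels[nonzero] = cls + offset
        for k in range(len(edges) - 1):
            sel = dist[nonzero][cls == k]
            if sel.size:
                classes.append((float(sel.min()), float(sel.max())))
            else:
                classes.append((np.nan, np.nan))
    return labels, classes


@dataclass
class Autocorrelogram:
    """Per-distance-class autocorrelation with permutation null bounds.

    ``table`` columns: d_min, d_max, n_pairs, r, null_low, null_high,
    participation, cv_participation.
    """

    table: pd.DataFrame
    permutations: int


def _class_diagnostics(pair_idx: np.ndarray, n_ind: int) -> tuple[float, float]:
    counts = np.bincount(pair_idx.ravel(), minlength=n_ind)
    participation = float((counts > 0).mean())
    mean = counts.mean()
    cv = float(counts.std() / mean) if mean > 0 else np.nan
    return participation, cv


def spatial_autocorrelogram(
    g: GenotypeMatrix,
    coords: np.ndarray,
    n_classes: int = 8,
    permutations: int = 9999,
    seed: int = 0,
    locations: np.ndarray | None = None,
) -> Autocorrelogram:
    """Multivariate spatial autocorrelogram (Smouse-Peakall construction).

    The coefficient per distance class is the ratio of summed off-diagonal
    to pairing-weighted diagonal entries of the double-centred genetic
    covariance matrix, restricted to pairs in the class.  The null
    envelope is the 2.5/97.5 percentile band of the coefficient under
    random shuffling of individual coordinates.  When ``locations`` labels
    sampling replicates, covariances are centred within each location and
    only within-location pairs are pooled across replicates (the
    "multi-pop" mode of the field tools).
    """
    coords = np.asarray(coords, dtype=float)
    n = g.n_individuals
    if coords.shape[0] != n:
        raise ValueError("one coordinate pair per individual required")
    if locations is None:
        locations = np.zeros(n, dtype=int)
    locations = np.asarray(locations)
    d2 = _genetic_sq_distance(g)

    # within-location centred covariance; geographic pair distances
    cmat = np.full((n, n), np.nan)
    geo = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    pair_i, pair_j = [], []
    for loc in np.unique(locations):
        idx = np.flatnonzero(locations == loc)
        if len(idx) < 2:
            continue
        cmat[np.ix_(idx, idx)] = _centered_covariance(d2[np.ix_(idx, idx)])
        ii, jj = np.triu_indices(len(idx), 1)
        pair_i.extend(idx[ii])
        pair_j.extend(idx[jj])
    pair_i = np.asarray(pair_i)
    pair_j = np.asarray(pair_j)
    pair_dist = geo[pair_i, pair_j]
    labels, classes = _equal_count_classes(pair_dist, n_classes)

    rng = np.random.default_rng(seed)
    perms = [np.arange(n)]
    for _ in range(permutations):
        p = np.arange(n)
        for loc in np.unique(locations):
            idx = np.flatnonzero(locations == loc)
            p[idx] = idx[rng.permutation(len(idx))]
        perms.append(p)

    diag = np.diag(cmat)
    rows = []
    for k, (dmin, dmax) in enumerate(classes):
        sel = labels == k
        if not sel.any():
            rows.append((dmin, dmax, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        pi, pj = pair_i[sel], pair_j[sel]
        w = np.bincount(np.concatenate([pi, pj]), minlength=n).astype(float)

        def coeff(perm):
            num = 2.0 * cmat[perm[pi], perm[pj]].sum()
            den = float(w @ diag[perm])
            return num / den if den != 0 else np.nan

        vals = np.array([coeff(p) for p in perms])
        r_obs = vals[0]
        null = vals[1:]
        lo, hi = (np.nanpercentile(null, [2.5, 97.5]) if null.size else (np.nan, np.nan))
        part, cv = _class_diagnostics(np.stack([pi, pj], axis=1), n)
        rows.append((dmin, dmax, int(sel.sum()), r_obs, lo, hi, part, cv))
    table = pd.DataFrame(
        rows,
        columns=[
            "d_min",
            "d_max",
            "n_pairs",
            "r",
            "null_low",
            "null_high",
            "participation",
            "cv_participation",
        ],
    )
    return Autocorrelogram(table, permutations)


class ClassDiagnosticsError(ValueError):
    """Distance-class diagnostics violated (pairs/participation/CV)."""


def class_relatedness_profile(
    g: GenotypeMatrix,
    coords: np.ndarray,
    n_classes: int = 8,
    permutations: int = 10000,
    estimators: tuple[str, ...] = ("qg", "lr", "loiselle"),
    seed: int = 0,
    override_diagnostics: bool = False,
    min_pairs: int = 100,
) -> pd.DataFrame:
    """Mean relatedness per distance class with permutation deviation tests.

    For each class the mean pairwise estimator value is compared with its
    distribution under random permutation of individual coordinates
    (two-sided, add-one-smoothed p).  Classes must satisfy the standard
    diagnostics — more than ``min_pairs`` pairwise comparisons,
    participation index > 50% and coefficient of variation of participation
    < 1 — unless ``override_diagnostics`` is set.
    """
    coords = np.asarray(coords, dtype=float)
    n = g.n_individuals
    geo = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    pi, pj = np.triu_indices(n, 1)
    labels, classes = _equal_count_classes(geo[pi, pj], n_classes)

    mats = {est: relatedness_matrix(g, est) for est in estimators}
    rng = np.random.default_rng(seed)
    perm_list = [np.arange(n)] + [rng.permutation(n) for _ in range(permutations)]

    problems = []
    rows = []
    for k, (dmin, dmax) in enumerate(classes):
        sel = labels == k
        npairs = int(sel.sum())
        part, cv = _class_diagnostics(np.stack([pi[sel], pj[sel]], axis=1), n)
        if npairs <= min_pairs:
            problems.append(f"class {k}: {npairs} pairs (need > {min_pairs})")
        if part <= 0.5:
            problems.append(f"class {k}: participation {part:.2f} (need > 0.5)")
        if not cv < 1.0:
            problems.append(f"class {k}: CV of participation {cv:.2f} (need < 1)")
        row = {"class": k, "d_min": dmin, "d_max": dmax, "n_pairs": npairs,
               "participation": part, "cv_participation": cv}
        for est in estimators:
            m = mats[est]
            vals = np.array(
                [np.nanmean(m[p[pi[sel]], p[pj[sel]]]) for p in perm_list]
            )
            obs, null = vals[0], vals[1:]
            ge = int(np.sum(null >= obs))
            le = int(np.sum(null <= obs))
            p2 = min(1.0, 2.0 * (min(ge, le) + 1) / (permutations + 1))
            row[f"{est}_mean"] = obs
            row[f"{est}_p"] = p2
            row[f"{est}_null_low"], row[f"{est}_null_high"] = np.percentile(
                null, [2.5, 97.5]
            )
        rows.append(row)
    if problems and not override_diagnostics:
        raise ClassDiagnosticsError(
            "distance-class diagnostics violated:\n" + "\n".join(problems)
        )
    return pd.DataFrame(rows)
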