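"""Per-locus / per-locality quality control for SSR genotypes.

Covers the standard pre-analysis battery for codominant markers:

* Brookfield null-allele frequency estimation from the He-Ho gap,
* Monte-Carlo chi-square tests of Hardy-Weinberg equilibrium,
* Benjamini-Hochberg multiple-testing correction (two families: per locus
  across localities, and per locality across loci),
* the standardized index of association (r̄d) as a multilocus linkage
  disequilibrium summary, with a permutation test,
* genotype accumulation curves (multilocus-genotype discrimination power).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .genotypes import MISSING, GenotypeDataset


@dataclass
class NullAlleleEstimate:
    locus: str
    locality: str
    r: float        # truncated at 0
    r_raw: float    # may be negative
    n: int


@dataclass
class HweResult:
    locus: str
    locality: str
    chi2: float
    p_mc: float
    p_adj: float | None
    n: int
    n_perm: int


@dataclass
class LdResult:
    scope: str
    rbar_d: float
    p_perm: float
    n_perm: int


@dataclass
class AccumulationCurve:
    n_loci_axis: np.ndarray          # x = 1..L-1
    counts: np.ndarray               # (L-1, n_resamples) MLG counts
    plateau: int

    @property
    def medians(self) -> np.ndarray:
        return np.median(self.counts, axis=1)


# ---------------------------------------------------------------------------
# Brookfield null alleles
# ---------------------------------------------------------------------------

def brookfield_null(ds: GenotypeDataset, locus, locality) -> NullAlleleEstimate | None:
    """Brookfield (estimator 1) null-allele frequency r = (He - Ho)/(1 + He).

    He is the plain expected heterozygosity from observed allele frequencies
    at the locus within the locality.  Returns ``None`` (skipped) for
    monomorphic loci; requires >= 5 complete genotypes.  The raw estimate is
    retained alongside the value truncated at zero.
    """
    j = ds.locus_names.index(locus) if isinstance(locus, str) else locus
    si = ds.samples_of(locality)
    pairs = ds.calls[si, j, :]
    pairs = pairs[pairs[:, 0] != MISSING]
    n = len(pairs)
    if n < 5:
        raise ValueError(f"need >= 5 complete genotypes at ({locus}, {locality}); got {n}")
    alleles, counts = np.unique(pairs.ravel(), return_counts=True)
    if len(alleles) < 2:
        return None
    p = counts / counts.sum()
    he = 1.0 - np.sum(p**2)
    ho = np.mean(pairs[:, 0] != pairs[:, 1])
    r_raw = (he - ho) / (1.0 + he)
    return NullAlleleEstimate(
        locus=ds.locus_names[j], locality=str(locality),
        r=max(0.0, float(r_raw)), r_raw=float(r_raw), n=n,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo HWE test
# ---------------------------------------------------------------------------

def _genotype_chi2(pairs: np.ndarray, alleles: np.ndarray) -> float:
    """Chi-square of observed genotype classes against HWE expectations."""
    n = len(pairs)
    A = len(alleles)
    code = {a: i for i, a in enumerate(alleles)}
    idx = np.vectorize(code.get)(pairs)
    idx.sort(axis=1)
    obs = np.zeros((A, A))
    np.add.at(obs, (idx[:, 0], idx[:, 1]), 1)
    counts = np.bincount(idx.ravel(), minlength=A)
    p = counts / (2 * n)
    exp = np.zeros((A, A))
    for i in range(A):
        exp[i, i] = n * p[i] ** 2
        for j in range(i + 1, A):
            exp[i, j] = 2 * n * p[i] * p[j]
    mask = exp > 0
    return float(np.sum((obs[mask] - exp[mask]) ** 2 / exp[mask]))


def hwe_test(ds: GenotypeDataset, locus, locality, n_perm: int = 1000,
             seed: int = 0) -> HweResult | None:
    """Monte-Carlo chi-square HWE test at one locus within one locality.

    The null distribution is built by shuffling the 2n observed gene copies
    and re-pairing them, which preserves allele frequencies exactly.  The
    p-value uses the (b + 1)/(n_perm + 1) correction.  Monomorphic loci are
    skipped (``None``).
    """
    import warnings
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse Monte-Carlo p-value")
    j = ds.locus_names.index(locus) if isinstance(locus, str) else locus
    si = ds.samples_of(locality) if locality is not None else np.arange(ds.n_samples)
    pairs = ds.calls[si, j, :]
    pairs = pairs[pairs[:, 0] != MISSING]
    n = len(pairs)
    alleles = np.unique(pairs.ravel())
    if len(alleles) < 2:
        return None
    chi2_obs = _genotype_chi2(pairs, alleles)
    # vectorized permutations: shuffle the 2n copies, re-pair, recount
    code = {a: i for i, a in enumerate(alleles)}
    copies = np.vectorize(code.get)(pairs).ravel()
    A = len(alleles)
    counts = np.bincount(copies, minlength=A)
    p = counts / (2 * n)
    exp = np.zeros((A, A))
    for i in range(A):
        exp[i, i] = n * p[i] ** 2
        for k in range(i + 1, A):
            exp[i, k] = 2 * n * p[i] * p[k]
    exp_flat = exp[np.triu_indices(A)]
    tri_code = np.full((A, A), -1, dtype=np.int64)
    tri_code[np.triu_indices(A)] = np.arange(len(exp_flat))
    rng = np.random.default_rng(seed)
    perms = np.tile(copies, (n_perm, 1))
    perms = rng.permuted(perms, axis=1).reshape(n_perm, n, 2)
    perms.sort(axis=2)
    cls = tri_code[perms[:, :, 0], perms[:, :, 1]]  # (n_perm, n)
    ncls = len(exp_flat)
    flat = cls + np.arange(n_perm)[:, None] * ncls
    obs = np.bincount(flat.ravel(), minlength=n_perm * ncls).reshape(n_perm, ncls)
    mask = exp_flat > 0
    chi2_perm = np.sum((obs[:, mask] - exp_flat[mask]) ** 2 / exp_flat[mask], axis=1)
    p_mc = (np.sum(chi2_perm >= chi2_obs - 1e-12) + 1) / (n_perm + 1)
    return HweResult(
        locus=ds.locus_names[j], locality=str(locality), chi2=chi2_obs,
        p_mc=float(p_mc), p_adj=None, n=n, n_perm=n_perm,
    )


def adjust_bh(pvals, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def hwe_table(ds: GenotypeDataset, n_perm: int = 1000, seed: int = 0,
              alpha: float = 0.05):
    """All locus x locality HWE tests with BH correction in two families.

    Returns a list of :class:`HweResult` where ``p_adj`` is the adjustment
    within the locality (across loci), plus a dict of per-locus families
    (across localities) with their own adjusted values — deviations seen
    "in more than one population" are read from the second family.
    """
    rng = np.random.default_rng(seed)
    results = []
    for loc in ds.locality_order():
        batch = []
        for j in range(ds.n_loci):
            r = hwe_test(ds, j, loc, n_perm=n_perm, seed=int(rng.integers(2**31)))
            if r is not None:
                batch.append(r)
        if batch:
            p_adj, _ = adjust_bh([r.p_mc for r in batch], alpha)
            for r, pa in zip(batch, p_adj):
                r.p_adj = float(pa)
        results.extend(batch)
    by_locus: dict = {}
    for r in results:
        by_locus.setdefault(r.locus, []).append(r)
    locus_family = {}
    for locus, rs in by_locus.items():
        p_adj, rej = adjust_bh([r.p_mc for r in rs], alpha)
        locus_family[locus] = {
            "localities": [r.locality for r in rs],
            "p_adj": p_adj.tolist(),
            "n_significant": int(rej.sum()),
        }
    return results, locus_family


# ---------------------------------------------------------------------------
# Index of association (r̄d)
# ---------------------------------------------------------------------------

def _pair_distances(calls: np.ndarray) -> np.ndarray:
    """Per-locus genetic distance for every sample pair.

    Distance at a locus is the number of allele differences between the two
    unordered genotypes scaled to {0, 0.5, 1}; pairs are compared only at
    loci complete in both samples (missing loci contribute 0 and are the
    caller's concern).  Returns (n_pairs, L).
    """
    n, L, _ = calls.shape
    ii, jj = np.triu_indices(n, k=1)
    a = calls[ii]  # (P, L, 2), sorted pairs
    b = calls[jj]
    # shared alleles between two sorted pairs (multiset intersection size)
    shared = np.zeros((len(ii), L))
    eq = (a[:, :, :, None] == b[:, :, None, :])  # (P, L, 2, 2)
    # multiset intersection of two size-2 multisets via greedy matching
    m00 = eq[:, :, 0, 0]
    m01 = eq[:, :, 0, 1]
    m10 = eq[:, :, 1, 0]
    m11 = eq[:, :, 1, 1]
    # best matching of {a0,a1} to {b0,b1}
    two = (m00 & m11) | (m01 & m10)
    one = m00 | m01 | m10 | m11
    shared = np.where(two, 2, np.where(one, 1, 0)).astype(float)
    dist = 1.0 - shared / 2.0
    miss = (a[:, :, 0] == MISSING) | (b[:, :, 0] == MISSING)
    dist[miss] = np.nan
    return dist


def _rbar_d_from_dist(dist: np.ndarray) -> float:
    """r̄d from a (n_pairs, L) per-locus pair-distance matrix."""
    d = np.nan_to_num(dist, nan=0.0)  # pairwise-complete: missing loci add 0
    total = d.sum(axis=1)
    v_o = np.var(total)
    v_i = np.var(d, axis=0)
    denom = 0.0
    L = d.shape[1]
    for i, j in combinations(range(L), 2):
        denom += np.sqrt(v_i[i] * v_i[j])
    if denom == 0:
        return float("nan")
    return float((v_o - v_i.sum()) / (2.0 * denom))


def index_of_association(ds: GenotypeDataset, scope=None, n_perm: int = 999,
                         seed: int = 0) -> LdResult:
    """Standardized index of association r̄d with a permutation test.

    ``scope``: ``None`` for the whole dataset, or a locality label.  The
    permutation null shuffles genotypes among individuals independently at
    each locus, destroying inter-locus association while preserving
    single-locus genotype frequencies.
    """
    si = np.arange(ds.n_samples) if scope is None else ds.samples_of(scope)
    if len(si) < 2:
        raise ValueError("scope needs at least 2 samples")
    calls = ds.calls[si]
    if calls.shape[1] < 2:
        raise ValueError("need at least 2 loci")
    dist = _pair_distances(calls)
    if np.nanmax(np.nan_to_num(dist, nan=0.0)) == 0:
        return LdResult(scope=str(scope), rbar_d=float("nan"), p_perm=float("nan"),
                        n_perm=0)
    obs = _rbar_d_from_dist(dist)
    rng = np.random.default_rng(seed)
    n = calls.shape[0]
    count = 0
    for _ in range(n_perm):
        shuf = np.empty_like(calls)
        for l in range(calls.shape[1]):
            shuf[:, l, :] = calls[rng.permutation(n), l, :]
        if _rbar_d_from_dist(_pair_distances(shuf)) >= obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return LdResult(scope="overall" if scope is None else str(scope),
                    rbar_d=float(obs), p_perm=float(p), n_perm=n_perm)


# ---------------------------------------------------------------------------
# Genotype accumulation
# ---------------------------------------------------------------------------

def _mlg_count(calls: np.ndarray, locus_idx) -> int:
    """Distinct multilocus genotypes over the given loci.

    A missing cell never matches anything (conservative splitting): two
    samples differing only by missingness count as distinct genotypes.
    """
    sub = calls[:, locus_idx, :]
    n = sub.shape[0]
    keys = []
    for i in range(n):
        row = sub[i]
        if (row[:, 0] == MISSING).any():
            # missing treated as a sample-unique state -> never matches
            keys.append(("!", i))
        else:
            keys.append(tuple(map(tuple, row)))
    return len(set(keys))


def genotype_accumulation(ds: GenotypeDataset, n_resamples: int = 1000,
                          seed: int = 0) -> AccumulationCurve:
    """Genotype accumulation curve: MLG counts over random locus subsets.

    For each x in 1..L-1, ``n_resamples`` random x-subsets of loci are drawn
    and the number of distinct multilocus genotypes counted.  The plateau is
    the MLG count using all loci.
    """
    L = ds.n_loci
    if L < 2:
        raise ValueError("need at least 2 loci")
    rng = np.random.default_rng(seed)
    xs = np.arange(1, L)
    counts = np.zeros((L - 1, n_resamples), dtype=int)
    for xi, x in enumerate(xs):
        for r in range(n_resamples):
            idx = rng.choice(L, size=x, replace=False)
            counts[xi, r] = _mlg_count(ds.calls, idx)
    plateau = _mlg_count(ds.calls, np.arange(L))
    return AccumulationCurve(n_loci_axis=xs, counts=counts, plateau=plateau)


def loci_for_full_discrimination(curve: AccumulationCurve) -> int | None:
    """Smallest x whose median MLG count reaches the plateau, if any."""
    med = curve.medians
    hit = np.flatnonzero(med >= curve.plateau)
    return int(curve.n_loci_axis[hit[0]]) if hit.size else None
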