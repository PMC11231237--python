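"""Hierarchical differentiation: Weir-Cockerham F-statistics, pairwise FST,
AMOVA, Mantel isolation-by-distance, PCA and DAPC.

The F-statistics follow the Weir & Cockerham (1984) variance-component
estimators: per locus and allele, components a (among populations),
b (among individuals within populations) and c (within individuals) are
computed from allele frequencies, heterozygote frequencies and sample
sizes; multilocus ratio estimators are

    theta (FST) = sum(a) / sum(a + b + c)
    F     (FIT) = 1 - sum(c) / sum(a + b + c)
    f     (FIS) = 1 - sum(c) / sum(b + c)

with percentile confidence intervals from bootstrap over loci.

AMOVA decomposes allele-identity mismatch distances between gene copies
into among-locality, among-individual-within-locality, and
within-individual components with Phi-statistics and permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import MISSING, GenotypeDataset


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

def _wc_components_locus(pairs_by_pop: list) -> tuple:
    """Per-allele summed (a, b, c) components at one locus.

    ``pairs_by_pop``: list of (n_i, 2) arrays of complete genotypes per
    population.  Populations with no complete genotypes are dropped; a
    monomorphic locus contributes (0, 0, 0).
    """
    pops = [p for p in pairs_by_pop if len(p) > 0]
    r = len(pops)
    if r < 2:
        return 0.0, 0.0, 0.0
    alleles = np.unique(np.concatenate([p.ravel() for p in pops]))
    if len(alleles) < 2:
        return 0.0, 0.0, 0.0
    n = np.array([len(p) for p in pops], dtype=float)
    nbar = n.mean()
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p_i = np.array([np.mean(p == al) for p in pops])  # allele freq per pop
        h_i = np.array([np.mean((p[:, 0] == al) ^ (p[:, 1] == al)) for p in pops])
        pbar = np.sum(n * p_i) / (r * nbar)
        s2 = np.sum(n * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n * h_i) / (r * nbar)
        if nbar <= 1:
            continue
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


@dataclass
class FHierarchy:
    f_is: float
    f_it: float
    f_st: float
    components: np.ndarray  # (L, 3) per-locus (a, b, c)
    ci: dict = field(default_factory=dict)  # stat -> (lo, hi)
    n_boot: int = 0


def _ratios_from_components(comp: np.ndarray) -> tuple:
    a, b, c = comp.sum(axis=0)
    tot = a + b + c
    if tot == 0 or (b + c) == 0:
        return float("nan"), float("nan"), float("nan")
    return 1.0 - c / (b + c), 1.0 - c / tot, a / tot  # f_is, f_it, f_st


def wc_f_statistics(ds: GenotypeDataset, grouping=None, n_boot: int = 10000,
                    seed: int = 0) -> FHierarchy:
    """Multilocus Weir-Cockerham F_IS / F_IT / F_ST with locus-bootstrap CIs.

    ``grouping``: per-sample labels (defaults to the dataset localities).
    """
    groups = list(ds.localities) if grouping is None else list(grouping)
    labels = sorted(set(groups), key=groups.index)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    garr = np.asarray(groups, dtype=object)
    idx_by_g = [np.flatnonzero(garr == lab) for lab in labels]
    comp = np.zeros((ds.n_loci, 3))
    for j in range(ds.n_loci):
        pops = []
        for gi in idx_by_g:
            pairs = ds.calls[gi, j, :]
            pops.append(pairs[pairs[:, 0] != MISSING])
        comp[j] = _wc_components_locus(pops)
    f_is, f_it, f_st = _ratios_from_components(comp)
    if np.isnan(f_st):
        raise ValueError("all loci monomorphic: F-statistics undefined")
    ci = {}
    if n_boot:
        rng = np.random.default_rng(seed)
        L = ds.n_loci
        boots = np.empty((n_boot, 3))
        draws = rng.integers(0, L, size=(n_boot, L))
        csum = comp[draws].sum(axis=1)  # (n_boot, 3)
        tot = csum.sum(axis=1)
        bc = csum[:, 1] + csum[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            boots[:, 0] = 1.0 - csum[:, 2] / bc
            boots[:, 1] = 1.0 - csum[:, 2] / tot
            boots[:, 2] = csum[:, 0] / tot
        for k, name in enumerate(("f_is", "f_it", "f_st")):
            vals = boots[:, k][np.isfinite(boots[:, k])]
            ci[name] = (float(np.percentile(vals, 2.5)),
                        float(np.percentile(vals, 97.5)))
    return FHierarchy(f_is=float(f_is), f_it=float(f_it), f_st=float(f_st),
                      components=comp, ci=ci, n_boot=n_boot)


@dataclass
class PairwiseFstMatrix:
    localities: list
    theta: np.ndarray        # raw (may be negative), symmetric, zero diagonal
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_boot: int
    excluded: list = field(default_factory=list)

    def clamped(self) -> np.ndarray:
        return np.maximum(self.theta, 0.0)


def pairwise_fst(ds: GenotypeDataset, n_boot: int = 10000, seed: int = 0) -> PairwiseFstMatrix:
    """Locality x locality multilocus theta with bootstrap CIs.

    Localities with fewer than 2 samples are excluded (reported in
    ``excluded``).  Negative point estimates are retained.
    """
    locs = [l for l in ds.locality_order() if len(ds.samples_of(l)) >= 2]
    excluded = [l for l in ds.locality_order() if l not in locs]
    if len(locs) < 2:
        raise ValueError("need >= 2 localities with >= 2 samples")
    m = len(locs)
    theta = np.zeros((m, m))
    lo = np.zeros((m, m))
    hi = np.zeros((m, m))
    rng = np.random.default_rng(seed)
    for i in range(m):
        for j in range(i + 1, m):
            si = np.concatenate([ds.samples_of(locs[i]), ds.samples_of(locs[j])])
            sub = ds.subset(si)
            fh = wc_f_statistics(sub, n_boot=n_boot, seed=int(rng.integers(2**31)))
            theta[i, j] = theta[j, i] = fh.f_st
            if fh.ci:
                lo[i, j] = lo[j, i] = fh.ci["f_st"][0]
                hi[i, j] = hi[j, i] = fh.ci["f_st"][1]
    return PairwiseFstMatrix(localities=locs, theta=theta, ci_lo=lo, ci_hi=hi,
                             n_boot=n_boot, excluded=excluded)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaTable:
    rows: list  # dicts: source, df, ss, variance, pct, phi, p
    n_perm: int

    def as_dict(self):
        return {"rows": self.rows, "n_perm": self.n_perm}


def _copy_matrix(ds: GenotypeDataset):
    """Gene-copy allele matrix (2N, L) with MISSING propagated, + owner index."""
    n, L, _ = ds.calls.shape
    copies = ds.calls.transpose(0, 2, 1).reshape(2 * n, L)  # rows: s0c0, s0c1, s1c0...
    owner = np.repeat(np.arange(n), 2)
    return copies, owner


def _identity_d2(copies, L):
    """Pairwise copy distances: loci with different alleles, pairwise-complete
    and rescaled to L loci (AMOVA squared distances)."""
    valid = copies != MISSING
    eqm = copies[:, None, :] != copies[None, :, :]
    both = valid[:, None, :] & valid[None, :, :]
    nshared = both.sum(axis=2)
    return np.where(nshared > 0,
                    (eqm & both).sum(axis=2) * (L / np.maximum(nshared, 1)), 0.0)


def _size_d2(copies, L):
    """R_ST-like squared distances: summed squared allele-size differences."""
    valid = copies != MISSING
    diff = (copies[:, None, :] - copies[None, :, :]).astype(float)
    both = valid[:, None, :] & valid[None, :, :]
    nshared = both.sum(axis=2)
    return np.where(nshared > 0,
                    np.where(both, diff**2, 0.0).sum(axis=2)
                    * (L / np.maximum(nshared, 1)), 0.0)


def amova(ds: GenotypeDataset, grouping=None, n_perm: int = 999, seed: int = 0,
          rst: bool = False) -> AmovaTable:
    """Three-level AMOVA (localities / individuals / gene copies).

    ``rst=True`` switches the copy distance to squared allele-size
    difference (R_ST-like); the default is allele identity (F_ST-like).
    Permutation p-values: individuals among localities for the
    among-locality component; gene copies among individuals (within
    localities) for the among-individual component; gene copies anywhere
    for the within-individual statistic.
    """
    groups = list(ds.localities) if grouping is None else list(grouping)
    if len(set(groups)) < 2:
        raise ValueError("AMOVA needs >= 2 groups")
    copies, owner = _copy_matrix(ds)
    L = ds.n_loci
    d2 = _size_d2(copies, L) if rst else _identity_d2(copies, L)

    obs = _components_from_d2(d2, owner, groups)
    sigma_a, sigma_b, sigma_c = obs["sigma"]
    total = sigma_a + sigma_b + sigma_c
    phi_st = (sigma_a + sigma_b) / total   # samples-total
    phi_sp = sigma_b / (sigma_b + sigma_c) # samples-within-localities
    phi_pt = sigma_a / total               # localities-total

    # permutation nulls: every scheme is an index permutation, so the copy
    # distance matrix is computed once and re-indexed
    rng = np.random.default_rng(seed)
    n_ind = ds.n_samples
    ge_a = ge_b = ge_c = 0
    for _ in range(n_perm):
        # level 1: permute individuals among localities (labels move)
        perm_groups = [groups[i] for i in rng.permutation(n_ind)]
        pa = _components_from_d2(d2, owner, perm_groups)["sigma"][0]
        if pa >= sigma_a - 1e-12:
            ge_a += 1
        # level 2: permute copies among individuals within localities
        pi = np.arange(2 * n_ind)
        garr = np.asarray(groups, dtype=object)
        for lab in set(groups):
            rowsel = np.flatnonzero(np.repeat(garr == lab, 2))
            pi[rowsel] = pi[rowsel[rng.permutation(len(rowsel))]]
        pb = _components_from_d2(d2[np.ix_(pi, pi)], owner, groups)["sigma"][1]
        if pb >= sigma_b - 1e-12:
            ge_b += 1
        # level 3: permute copies among all individuals
        pi2 = rng.permutation(2 * n_ind)
        pc = _components_from_d2(d2[np.ix_(pi2, pi2)], owner, groups)["sigma"]
        if (pc[0] + pc[1]) >= (sigma_a + sigma_b) - 1e-12:
            ge_c += 1
    p_a = (ge_a + 1) / (n_perm + 1)
    p_b = (ge_b + 1) / (n_perm + 1)
    p_c = (ge_c + 1) / (n_perm + 1)

    ss = obs["ss"]
    df = obs["df"]
    pct = [100 * sigma_a / total, 100 * sigma_b / total, 100 * sigma_c / total]
    rows = [
        {"source": "among localities", "df": df[0], "ss": ss[0],
         "variance": sigma_a, "pct": pct[0], "phi": phi_pt, "p": p_a},
        {"source": "among samples within localities", "df": df[1], "ss": ss[1],
         "variance": sigma_b, "pct": pct[1], "phi": phi_sp, "p": p_b},
        {"source": "within samples", "df": df[2], "ss": ss[2],
         "variance": sigma_c, "pct": pct[2], "phi": phi_st, "p": p_c},
        {"source": "total", "df": df[3], "ss": ss[3],
         "variance": total, "pct": 100.0, "phi": float("nan"), "p": float("nan")},
    ]
    return AmovaTable(rows=rows, n_perm=n_perm)


def _components_from_d2(d2, owner, group_of_ind):
    """Nested sums of squares and variance components from copy distances.

    Copy rows are assumed adjacent per individual (2i, 2i+1), as produced
    by :func:`_copy_matrix`.
    """
    n_copies = d2.shape[0]
    n_ind = len(group_of_ind)
    groups = np.asarray([group_of_ind[o] for o in owner], dtype=object)
    labels = sorted(set(group_of_ind), key=list(group_of_ind).index)

    def ss_group(idx):
        if len(idx) == 0:
            return 0.0
        return float(d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx)))

    ss_total = float(d2.sum() / (2.0 * n_copies))
    ss_wloc = sum(ss_group(np.flatnonzero(groups == lab)) for lab in labels)
    even = np.arange(0, n_copies, 2)
    ss_wind = float(d2[even, even + 1].sum() / 2.0)
    ss_among_loc = ss_total - ss_wloc
    ss_among_ind = ss_wloc - ss_wind
    G = len(labels)
    df_a, df_b, df_c = G - 1, n_ind - G, n_ind
    ms_a = ss_among_loc / df_a if df_a else float("nan")
    ms_b = ss_among_ind / df_b if df_b else float("nan")
    ms_c = ss_wind / df_c
    sigma_c = ms_c
    sigma_b = (ms_b - sigma_c) / 2.0 if df_b else 0.0
    sizes = np.array([np.sum(groups == lab) for lab in labels], dtype=float)
    n_c = (n_copies - np.sum(sizes**2) / n_copies) / df_a if df_a else float("nan")
    sigma_a = (ms_a - sigma_c - 2 * sigma_b) / n_c if df_a else 0.0
    return {"ss": (ss_among_loc, ss_among_ind, ss_wind, ss_total),
            "df": (df_a, df_b, df_c, df_a + df_b + df_c),
            "sigma": (sigma_a, sigma_b, sigma_c)}


# ---------------------------------------------------------------------------
# Mantel isolation by distance
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    r_squared: float
    p: float
    n_perm: int


def mantel_ibd(fst: PairwiseFstMatrix, coords: dict, n_perm: int = 999,
               seed: int = 0) -> MantelResult:
    """Mantel test of linearized FST against Euclidean coordinate distance.

    Genetic distance is theta/(1-theta) on the zero-clamped matrix;
    geographic distance is Euclidean on (lat, lon) as given.  The test
    statistic is the Pearson correlation of off-diagonal entries; the null
    permutes locality labels of one matrix.
    """
    locs = fst.localities
    missing = [l for l in locs if l not in coords]
    if missing:
        raise ValueError(f"no coordinates for localities: {missing}")
    theta = fst.clamped()
    if (theta >= 1.0).any():
        i, j = np.argwhere(theta >= 1.0)[0]
        raise ValueError(f"theta = 1 between {locs[i]} and {locs[j]}: "
                         "linearized distance infinite")
    gen = theta / (1.0 - theta)
    xy = np.array([coords[l] for l in locs], dtype=float)
    geo = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    iu = np.triu_indices(len(locs), k=1)
    gv, dv = gen[iu], geo[iu]
    if np.std(gv) == 0 or np.std(dv) == 0:
        raise ValueError("degenerate (constant) distance matrix")
    r_obs = float(np.corrcoef(gv, dv)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    m = len(locs)
    for _ in range(n_perm):
        perm = rng.permutation(m)
        gp = gen[np.ix_(perm, perm)][iu]
        if np.corrcoef(gp, dv)[0, 1] >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, r_squared=r_obs**2, p=float(p), n_perm=n_perm)


# ---------------------------------------------------------------------------
# PCA / DAPC
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray
    pct_variance: np.ndarray


@dataclass
class DapcResult:
    groups: list
    scores: np.ndarray          # discriminant-axis coordinates
    membership: np.ndarray      # (n, G) posterior group probabilities
    assigned: np.ndarray        # predicted group label per sample
    n_pcs: int
    n_da: int


def indicator_matrix(ds: GenotypeDataset) -> np.ndarray:
    """One column per (locus, allele): allele dosage 0/1/2, NaN if missing."""
    cols = []
    for j in range(ds.n_loci):
        pairs = ds.calls[:, j, :]
        alleles = np.unique(pairs[pairs != MISSING])
        miss = pairs[:, 0] == MISSING
        for a in alleles:
            dose = (pairs == a).sum(axis=1).astype(float)
            dose[miss] = np.nan
            cols.append(dose)
    return np.column_stack(cols) if cols else np.empty((ds.n_samples, 0))


def pca(ds: GenotypeDataset, n_axes: int | None = None) -> PcaResult:
    """PCA of the column-mean-imputed, centered allele dosage matrix."""
    if ds.n_samples < 2:
        raise ValueError("need >= 2 samples")
    X = indicator_matrix(ds)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X) - mu
    if X.size == 0 or np.allclose(X, 0):
        raise ValueError("constant data matrix: no axes")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    var = S**2 / (X.shape[0] - 1)
    pct = 100 * var / var.sum()
    k = len(S) if n_axes is None else min(n_axes, len(S))
    return PcaResult(scores=U[:, :k] * S[:k], loadings=Vt[:k].T,
                     pct_variance=pct[:k])


def dapc(ds: GenotypeDataset, groups, n_pcs: int | None = None,
         n_da: int | None = None) -> DapcResult:
    """Discriminant analysis of principal components.

    PCA reduction to ``n_pcs`` (default: enough axes for >= 80% of variance)
    followed by linear discriminant analysis on the group labels; membership
    probabilities come from the discriminant-space Gaussian model.
    """
    groups = list(groups)
    if len(groups) != ds.n_samples:
        raise ValueError("groups must cover all samples")
    labels = sorted(set(groups), key=groups.index)
    counts = {lab: groups.count(lab) for lab in labels}
    tiny = [lab for lab, c in counts.items() if c < 2]
    if tiny:
        raise ValueError(f"groups with a single sample: {tiny}")
    full = pca(ds)
    if n_pcs is None:
        cum = np.cumsum(full.pct_variance)
        n_pcs = int(np.searchsorted(cum, 80.0) + 1)
    n_pcs = min(n_pcs, ds.n_samples - len(labels), full.scores.shape[1])
    if n_pcs < 1:
        raise ValueError("too few samples for the requested reduction")
    X = full.scores[:, :n_pcs]
    n_da = min(len(labels) - 1, n_pcs) if n_da is None else min(n_da, len(labels) - 1)
    lda = LinearDiscriminantAnalysis(n_components=n_da)
    lda.fit(X, groups)
    return DapcResult(groups=labels, scores=lda.transform(X),
                      membership=lda.predict_proba(X),
                      assigned=lda.predict(X), n_pcs=n_pcs, n_da=n_da)
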