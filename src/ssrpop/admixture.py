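"""Bayesian admixture clustering with correlated allele frequencies.

A Gibbs sampler over the classical admixture model: each gene copy has a
latent cluster of origin Z; cluster allele frequencies P follow the
correlated-frequencies "F-model" (per-cluster drift from a common ancestral
frequency vector, Dirichlet(p_A * (1 - F_k) / F_k)); per-sample ancestry
vectors Q have a symmetric Dirichlet(alpha) prior with alpha sampled by a
Metropolis step.  The marginal likelihood ln Pr(data | K) is approximated
by the usual deviance estimator mean(lnL) - var(lnL)/2 over post-burn-in
sweeps, which feeds mean-LnP(K) and Evanno's delta-K model choice.  Label
switching across runs is resolved by optimal column permutation
(CLUMPP-style Frobenius agreement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotypes import MISSING, GenotypeDataset


@dataclass
class AdmixtureRun:
    k: int
    q: np.ndarray            # (n_samples, K) posterior mean ancestry
    p: np.ndarray            # (K, n_loci, n_alleles) posterior mean frequencies
    ln_p: float              # estimated ln Pr(data | K)
    alpha: float             # posterior mean Dirichlet concentration
    iters: int
    burnin: int
    seed: int
    sample_ids: list = field(default_factory=list)


@dataclass
class KSelection:
    ks: list
    mean_lnp: dict
    sd_lnp: dict
    delta_k: dict
    best_k_delta: int | None
    best_k_lnp: int


def _encode(ds: GenotypeDataset):
    """Allele-index matrix (n, L, 2) with -1 for missing, plus allele lists."""
    n, L, _ = ds.calls.shape
    aidx = np.full((n, L, 2), -1, dtype=np.int64)
    alleles = []
    for j in range(L):
        col = ds.calls[:, j, :]
        al = np.unique(col[col != MISSING])
        alleles.append(al)
        lut = {a: i for i, a in enumerate(al)}
        for c in range(2):
            vals = col[:, c]
            ok = vals != MISSING
            aidx[ok, j, c] = [lut[v] for v in vals[ok]]
    return aidx, alleles


def run_admixture(ds: GenotypeDataset, K: int, iters: int = 2000,
                  burnin: int = 500, seed: int = 0, thin: int = 5,
                  use_origin_prior: bool = False,
                  origin_prior_weight: float = 5.0,
                  init: str = "kmeans") -> AdmixtureRun:
    """One MCMC run of the admixture model at a fixed K.

    ``iters`` counts post-burn-in sweeps; states are averaged every ``thin``
    sweeps.  With ``use_origin_prior`` the ancestry prior of each sample is
    softly biased toward its locality's current mean ancestry (a LOCPRIOR-
    like soft prior, not migrant-ancestry modelling); default off.

    ``init='kmeans'`` seeds the chain from a k-means partition of the allele
    dosage matrix (run-to-run variation comes from ``seed``), which greatly
    reduces the chance of a chain stranded in a label-degenerate mode at
    desk-scale sweep counts; ``init='random'`` gives the classical diffuse
    start.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if ds.n_samples == 0:
        raise ValueError("empty dataset")
    aidx, alleles = _encode(ds)
    n, L, _ = aidx.shape
    n_mlg = len({tuple(map(tuple, ds.calls[i])) for i in range(n)})
    if K > n_mlg:
        raise ValueError(f"K={K} exceeds the {n_mlg} distinct multilocus genotypes")
    Amax = max(len(a) for a in alleles)
    rng = np.random.default_rng(seed)

    obs = aidx[:, :, :]                       # (n, L, 2)
    mask = obs >= 0
    li = np.broadcast_to(np.arange(L)[None, :, None], obs.shape)
    safe_obs = np.where(mask, obs, 0)

    # empirical ancestral frequencies for the F-model prior
    p_anc = np.full((L, Amax), 1e-9)
    for j in range(L):
        cnt = np.bincount(obs[:, j, :][mask[:, j, :]], minlength=Amax).astype(float)
        tot = cnt.sum()
        p_anc[j, : len(alleles[j])] = (cnt[: len(alleles[j])] + 0.5) / (tot + 0.5 * len(alleles[j]))

    if K == 1:
        q = np.ones((n, 1))
        p = np.zeros((1, L, Amax))
        lnl = 0.0
        for j in range(L):
            cnt = np.bincount(obs[:, j, :][mask[:, j, :]], minlength=Amax).astype(float)
            freq = (cnt + 1e-9) / max(cnt.sum(), 1)
            p[0, j] = freq
            lnl += float(np.log(freq[obs[:, j, :][mask[:, j, :]]]).sum())
        return AdmixtureRun(k=1, q=q, p=p, ln_p=lnl, alpha=float("nan"),
                            iters=iters, burnin=burnin, seed=seed,
                            sample_ids=list(ds.sample_ids))

    # state init
    pad_mask = np.zeros((L, Amax), dtype=bool)
    for j in range(L):
        pad_mask[j, : len(alleles[j])] = True
    if init == "kmeans":
        labels = _kmeans_labels(obs, mask, L, Amax, K, seed)
        Q = np.full((n, K), 0.1 / max(K - 1, 1))
        Q[np.arange(n), labels] = 0.9
        Q /= Q.sum(axis=1, keepdims=True)
        cnt0 = np.zeros((K, L, Amax))
        for k in range(K):
            sel = mask & (labels[:, None, None] == k)
            flat = li[sel] * Amax + safe_obs[sel]
            cnt0[k] = np.bincount(flat, minlength=L * Amax).reshape(L, Amax)
        P = np.where(pad_mask[None], cnt0 + 0.5, 0.0)
        P /= np.maximum(P.sum(axis=2, keepdims=True), 1e-300)
    else:
        g0 = rng.gamma(1.0, size=(K, L, Amax)) * pad_mask
        P = g0 / np.maximum(g0.sum(axis=2, keepdims=True), 1e-300)
        Q = rng.dirichlet(np.ones(K), size=n)
    alpha = 1.0
    F = np.full(K, 0.1)  # per-cluster drift
    loc_idx = np.array([ds.locality_order().index(l) for l in ds.localities])
    n_loc = loc_idx.max() + 1

    q_acc = np.zeros((n, K))
    p_acc = np.zeros((K, L, Amax))
    a_acc = 0.0
    lnl_trace = []
    n_states = 0
    total = burnin + iters
    for sweep in range(total):
        # --- Z | Q, P --------------------------------------------------
        lik = P[:, np.arange(L)[None, :, None], safe_obs]  # (K, n, L, 2)
        w = lik * Q.T[:, :, None, None]
        wsum = w.sum(axis=0)
        w /= np.maximum(wsum, 1e-300)
        u = rng.random((n, L, 2))
        cum = np.cumsum(w, axis=0)
        Z = (u[None] > cum).sum(axis=0)  # (n, L, 2)
        # --- P | Z (conjugate Dirichlet via gamma draws) ---------------
        zm = np.where(mask, Z, -1)
        cnt = np.zeros((K, L, Amax))
        for k in range(K):
            sel = zm == k
            flat = li[sel] * Amax + safe_obs[sel]
            cnt[k] = np.bincount(flat, minlength=L * Amax).reshape(L, Amax)
        lam = p_anc[None] * ((1.0 - F) / F)[:, None, None]
        shape = np.where(pad_mask[None], lam + cnt + 1e-9, 1e-12)
        g = rng.gamma(shape) * pad_mask[None]
        P = g / np.maximum(g.sum(axis=2, keepdims=True), 1e-300)
        # --- F | P (Metropolis, uniform prior on (0.001, 0.999)) -------
        logx = np.where(pad_mask[None], np.log(np.maximum(P, 1e-12)), 0.0)
        for k in range(K):
            prop = F[k] * np.exp(rng.normal(0, 0.2))
            if not (0.001 < prop < 0.999):
                continue
            cur_ll = _fmodel_loglik(logx[k], p_anc, pad_mask, F[k])
            prop_ll = _fmodel_loglik(logx[k], p_anc, pad_mask, prop)
            # lognormal proposal -> Jacobian term log(prop/F[k])
            if np.log(rng.random()) < prop_ll - cur_ll + np.log(prop / F[k]):
                F[k] = prop
        # --- Q | Z -----------------------------------------------------
        cnts = np.zeros((n, K))
        for k in range(K):
            cnts[:, k] = (zm == k).sum(axis=(1, 2))
        prior = np.full((n, K), alpha)
        if use_origin_prior:
            loc_mean = np.zeros((n_loc, K))
            for g in range(n_loc):
                loc_mean[g] = Q[loc_idx == g].mean(axis=0)
            prior = alpha * (1.0 + origin_prior_weight * loc_mean[loc_idx])
        Q = rng.gamma(prior + cnts) + 1e-12
        Q /= Q.sum(axis=1, keepdims=True)
        # --- alpha (Metropolis, uniform prior on (0, 10]) ---------------
        if not use_origin_prior:
            prop = alpha * np.exp(rng.normal(0, 0.3))
            if 0 < prop <= 10.0:
                cur = _sym_dirichlet_loglik(Q, alpha)
                new = _sym_dirichlet_loglik(Q, prop)
                if np.log(rng.random()) < new - cur + np.log(prop / alpha):
                    alpha = prop
        # --- bookkeeping ----------------------------------------------
        if sweep >= burnin:
            ll = float(np.log(np.maximum(wsum[mask], 1e-300)).sum())
            lnl_trace.append(ll)
            if (sweep - burnin) % thin == 0:
                q_acc += Q
                p_acc += P
                a_acc += alpha
                n_states += 1
    lnl_trace = np.array(lnl_trace)
    ln_p = float(lnl_trace.mean() - lnl_trace.var() / 2.0)
    return AdmixtureRun(
        k=K, q=q_acc / n_states, p=p_acc / n_states, ln_p=ln_p,
        alpha=a_acc / n_states, iters=iters, burnin=burnin, seed=seed,
        sample_ids=list(ds.sample_ids),
    )


def _kmeans_labels(obs, mask, L, Amax, K, seed):
    """K-means partition of the (mean-imputed) allele dosage matrix."""
    from sklearn.cluster import KMeans

    n = obs.shape[0]
    dose = np.zeros((n, L * Amax))
    rows = np.repeat(np.arange(n), 2 * L)
    cols = (np.broadcast_to(np.arange(L)[None, :, None], obs.shape) * Amax + obs)
    ok = mask.ravel()
    np.add.at(dose, (rows[ok], cols.ravel()[ok]), 1.0)
    seen = mask[:, :, 0] | mask[:, :, 1]
    wcol = np.repeat(seen, Amax, axis=1)
    colmean = np.where(wcol.sum(axis=0) > 0,
                       dose.sum(axis=0) / np.maximum(wcol.sum(axis=0), 1), 0.0)
    dose = np.where(wcol, dose, colmean[None, :])
    km = KMeans(n_clusters=K, n_init=5, random_state=seed % (2**31))
    return km.fit_predict(dose)


def _fmodel_loglik(logx_k, p_anc, pad_mask, f):
    """Summed Dirichlet log-density of one cluster's frequencies under the
    F-model prior with drift ``f`` (vectorized over loci)."""
    from scipy.special import gammaln
    conc = np.where(pad_mask, np.maximum(p_anc * (1.0 - f) / f, 1e-6), 0.0)
    per_locus = (gammaln(conc.sum(axis=1))
                 - np.where(pad_mask, gammaln(np.maximum(conc, 1e-300)), 0.0).sum(axis=1)
                 + ((conc - 1.0) * logx_k * pad_mask).sum(axis=1))
    return float(per_locus.sum())


def _sym_dirichlet_loglik(Q, alpha):
    from scipy.special import gammaln
    n, K = Q.shape
    return float(n * (gammaln(K * alpha) - K * gammaln(alpha))
                 + (alpha - 1.0) * np.log(np.maximum(Q, 1e-300)).sum())


# ---------------------------------------------------------------------------
# K selection (Evanno delta-K and mean LnP)
# ---------------------------------------------------------------------------

def select_k(runs: list) -> KSelection:
    """Evanno's delta-K and mean-LnP(K) model choice over a set of runs.

    ``runs``: AdmixtureRun objects covering a contiguous K range with >= 3
    runs per K (needed for the s.d.).  delta-K(K) = |L(K+1) - 2 L(K) +
    L(K-1)| / s.d.(L(K)) on the per-K means; undefined at the range ends
    and wherever the s.d. is zero.
    """
    by_k: dict = {}
    for r in runs:
        by_k.setdefault(r.k, []).append(r.ln_p)
    ks = sorted(by_k)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    mean_lnp = {k: float(np.mean(by_k[k])) for k in ks}
    sd_lnp = {k: float(np.std(by_k[k], ddof=1)) if len(by_k[k]) > 1 else 0.0
              for k in ks}
    delta_k = {}
    for i, k in enumerate(ks):
        if i == 0 or i == len(ks) - 1:
            continue
        if ks[i - 1] != k - 1 or ks[i + 1] != k + 1:
            continue
        if sd_lnp[k] == 0:
            delta_k[k] = float("nan")
            continue
        delta_k[k] = abs(mean_lnp[k + 1] - 2 * mean_lnp[k] + mean_lnp[k - 1]) / sd_lnp[k]
    finite = {k: v for k, v in delta_k.items() if np.isfinite(v)}
    best_delta = max(finite, key=finite.get) if finite else None
    best_lnp = max(mean_lnp, key=mean_lnp.get)
    return KSelection(ks=ks, mean_lnp=mean_lnp, sd_lnp=sd_lnp, delta_k=delta_k,
                      best_k_delta=best_delta, best_k_lnp=best_lnp)


# ---------------------------------------------------------------------------
# Run alignment (label switching)
# ---------------------------------------------------------------------------

def align_runs(runs: list):
    """Align cluster labels across runs at a fixed K; consensus Q.

    The first run is the reference; each other run's columns are permuted
    to maximize the Frobenius agreement of the Q matrices (CLUMPP's G
    similarity).  The assignment problem is solved exactly.  Returns
    ``(permutations, consensus_q)`` where ``permutations[r][k]`` is the
    reference column matched by run r's column k.
    """
    if len(runs) < 2:
        raise ValueError("need >= 2 runs to align")
    K = runs[0].k
    if any(r.k != K for r in runs):
        raise ValueError("runs must share K")
    if any(r.sample_ids != runs[0].sample_ids for r in runs):
        raise ValueError("runs must share the sample order")
    import warnings
    if K > 8:
        warnings.warn("large K: column matching may be slow/ambiguous")
    ref = runs[0].q
    perms = [np.arange(K)]
    aligned = [ref]
    for r in runs[1:]:
        # cost = squared distance between columns; minimize
        cost = ((r.q[:, :, None] - ref[:, None, :]) ** 2).sum(axis=0)
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(K, dtype=int)
        perm[rows] = cols  # run column k -> reference column perm[k]
        out = np.zeros_like(r.q)
        for k in range(K):
            out[:, perm[k]] = r.q[:, k]
        perms.append(perm)
        aligned.append(out)
    consensus = np.mean(aligned, axis=0)
    return perms, consensus
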