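from itertools import combinations

import numpy as np
import pytest

from ssrpop.genotypes import MISSING, GenotypeDataset
from ssrpop.differentiation import (
    amova,
    dapc,
    mantel_ibd,
    pairwise_fst,
    pca,
    wc_f_statistics,
)
from ssrpop.simulate import PopulationTemplate, make_ancestral_pools, sample_dataset

from conftest import random_dataset


# ---------------------------------------------------------------------------
# Independent Weir-Cockerham oracle: explicit loops straight from the
# textbook component formulas, one allele at a time.
# ---------------------------------------------------------------------------

def _wc_oracle(pops_by_locus):
    A = B = C = 0.0
    for pops in pops_by_locus:
        pops = [np.asarray(p) for p in pops if len(p) > 0]
        r = len(pops)
        if r < 2:
            continue
        alleles = sorted({a for p in pops for a in p.ravel()})
        if len(alleles) < 2:
            continue
        n = [len(p) for p in pops]
        nbar = sum(n) / r
        if nbar <= 1:  # a single genotype per population carries no signal
            continue
        nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
        for al in alleles:
            p_i = [np.mean(p == al) for p in pops]
            h_i = [np.mean((p[:, 0] == al) != (p[:, 1] == al)) for p in pops]
            pbar = sum(ni * pi for ni, pi in zip(n, p_i)) / (r * nbar)
            s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_i)) / ((r - 1) * nbar)
            hbar = sum(ni * hi for ni, hi in zip(n, h_i)) / (r * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                               / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            A += a
            B += b
            C += c
    tot = A + B + C
    return 1 - C / (B + C), 1 - C / tot, A / tot  # f_is, f_it, f_st


def _pops_by_locus(ds):
    out = []
    garr = np.asarray(ds.localities, dtype=object)
    labels = list(dict.fromkeys(ds.localities))
    for j in range(ds.n_loci):
        pops = []
        for lab in labels:
            pairs = ds.calls[np.flatnonzero(garr == lab), j, :]
            pops.append(pairs[pairs[:, 0] != MISSING])
        out.append(pops)
    return out


class TestWeirCockerham:
    def test_textbook_toy(self):
        # pop1: 10 AA, 10 Aa; pop2: 5 Aa, 15 aa
        g1 = [(1, 1)] * 10 + [(1, 2)] * 10
        g2 = [(1, 2)] * 5 + [(2, 2)] * 15
        calls = np.array(g1 + g2, np.int32)[:, None, :]
        ds = GenotypeDataset([f"s{i}" for i in range(40)], ["L1"], calls,
                             ["p1"] * 20 + ["p2"] * 20)
        fh = wc_f_statistics(ds, n_boot=0)
        f_is, f_it, f_st = _wc_oracle(_pops_by_locus(ds))
        assert fh.f_is == pytest.approx(f_is, abs=1e-12)
        assert fh.f_it == pytest.approx(f_it, abs=1e-12)
        assert fh.f_st == pytest.approx(f_st, abs=1e-12)

    def test_identical_populations_theta_near_zero(self, rng):
        base = random_dataset(rng, n_samples=12, n_loci=4, n_localities=1)
        calls = np.concatenate([base.calls, base.calls])
        ds = GenotypeDataset([f"s{i}" for i in range(24)], base.locus_names,
                             calls, ["a"] * 12 + ["b"] * 12)
        fh = wc_f_statistics(ds, n_boot=0)
        assert fh.f_st < 1e-9  # duplicated groups: no differentiation signal

    def test_matches_oracle_on_random_datasets(self, rng):
        """Machine-precision agreement with the loop-based oracle."""
        for _ in range(200):
            ds = random_dataset(rng, n_samples=int(rng.integers(6, 12)),
                                n_loci=int(rng.integers(1, 4)),
                                n_localities=int(rng.integers(2, 4)),
                                missing_rate=0.1)
            try:
                fh = wc_f_statistics(ds, n_boot=0)
            except ValueError:
                continue
            f_is, f_it, f_st = _wc_oracle(_pops_by_locus(ds))
            assert fh.f_st == pytest.approx(f_st, abs=1e-10)
            assert fh.f_it == pytest.approx(f_it, abs=1e-10)
            assert fh.f_is == pytest.approx(f_is, abs=1e-10)

    def test_bootstrap_ci_contains_point(self, preset):
        ds, _ = preset
        fh = wc_f_statistics(ds, n_boot=500, seed=1)
        for name, val in (("f_is", fh.f_is), ("f_it", fh.f_it), ("f_st", fh.f_st)):
            lo, hi = fh.ci[name]
            assert lo <= val <= hi


class TestPairwiseFst:
    def test_symmetry_zero_diagonal(self, preset):
        ds, _ = preset
        pw = pairwise_fst(ds, n_boot=0)
        assert np.allclose(pw.theta, pw.theta.T)
        assert np.allclose(np.diag(pw.theta), 0)

    def test_matches_pair_recomputation(self, rng):
        ds = random_dataset(rng, n_samples=18, n_loci=3, n_localities=3)
        pw = pairwise_fst(ds, n_boot=0)
        for i, j in combinations(range(len(pw.localities)), 2):
            si = np.concatenate([ds.samples_of(pw.localities[i]),
                                 ds.samples_of(pw.localities[j])])
            fh = wc_f_statistics(ds.subset(si), n_boot=0)
            assert pw.theta[i, j] == pytest.approx(fh.f_st, abs=1e-12)

    def test_andes_pool_most_divergent(self, preset):
        """Largest pairwise theta involves the Andes-like locality."""
        ds, _ = preset
        pw = pairwise_fst(ds, n_boot=0)
        i, j = np.unravel_index(np.argmax(pw.theta), pw.theta.shape)
        assert "PER-AND" in (pw.localities[i], pw.localities[j])


# ---------------------------------------------------------------------------
# AMOVA oracle: explicit squared-distance decomposition
# ---------------------------------------------------------------------------

def _amova_oracle(ds, groups):
    n, L, _ = ds.calls.shape
    copies = ds.calls.transpose(0, 2, 1).reshape(2 * n, L)
    owner = np.repeat(np.arange(n), 2)

    def dist(u, v):
        d = 0.0
        m = 0
        for l in range(L):
            if copies[u, l] == MISSING or copies[v, l] == MISSING:
                continue
            m += 1
            d += copies[u, l] != copies[v, l]
        return d * (L / m) if m else 0.0

    nc = 2 * n
    D = np.zeros((nc, nc))
    for u in range(nc):
        for v in range(u + 1, nc):
            D[u, v] = D[v, u] = dist(u, v)

    def ss(idx):
        tot = 0.0
        for u, v in combinations(idx, 2):
            tot += D[u, v]
        return tot / len(idx)

    labels = list(dict.fromkeys(groups))
    ss_total = ss(range(nc))
    ss_wloc = sum(ss([c for c in range(nc) if groups[owner[c]] == lab])
                  for lab in labels)
    ss_wind = sum(ss([2 * i, 2 * i + 1]) for i in range(n))
    return ss_total - ss_wloc, ss_wloc - ss_wind, ss_wind, ss_total


class TestAmova:
    def test_tiny_dataset_matches_oracle(self, rng):
        for _ in range(20):
            ds = random_dataset(rng, n_samples=6, n_loci=2, n_localities=2,
                                missing_rate=0.1)
            res = amova(ds, n_perm=0, seed=0)
            ss = [r["ss"] for r in res.rows]
            oracle = _amova_oracle(ds, ds.localities)
            for mine, ref in zip(ss, oracle):
                assert mine == pytest.approx(ref, abs=1e-10)

    def test_pct_variance_sums_to_100(self, preset):
        ds, _ = preset
        res = amova(ds, n_perm=0)
        assert sum(r["pct"] for r in res.rows[:3]) == pytest.approx(100.0)

    def test_phi_st_identity(self, preset):
        """Phi(samples-total) equals 1 - within-sample / total variance."""
        ds, _ = preset
        res = amova(ds, n_perm=0)
        sigma = [r["variance"] for r in res.rows[:3]]
        phi_st = res.rows[2]["phi"]
        assert phi_st == pytest.approx((sigma[0] + sigma[1]) / sum(sigma),
                                       abs=1e-12)

    def test_df_sum(self, rng):
        ds = random_dataset(rng, n_samples=10, n_loci=3, n_localities=2)
        res = amova(ds, n_perm=0)
        assert res.rows[3]["df"] == sum(r["df"] for r in res.rows[:3])
        assert res.rows[3]["df"] == 2 * ds.n_samples - 1

    def test_permutation_p_significant_for_structure(self, preset):
        ds, _ = preset
        sub = ds.subset(np.arange(0, ds.n_samples, 4))  # thin for speed
        res = amova(sub, n_perm=99, seed=0)
        assert res.rows[0]["p"] <= 0.05


class TestMantel:
    def _pw(self, theta, locs):
        from ssrpop.differentiation import PairwiseFstMatrix
        z = np.zeros_like(theta)
        return PairwiseFstMatrix(localities=locs, theta=theta, ci_lo=z,
                                 ci_hi=z, n_boot=0)

    def test_perfect_correlation(self):
        locs = ["a", "b", "c", "d"]
        coords = {"a": (0, 0), "b": (0, 3), "c": (4, 0), "d": (3, 4)}
        xy = np.array([coords[l] for l in locs], float)
        geo = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        theta = geo / (geo + 10)  # monotone increasing map -> linearized ~ geo
        theta = (geo / 20) / (1 + geo / 20)  # exactly linearized = geo/20
        np.fill_diagonal(theta, 0)
        res = mantel_ibd(self._pw(theta, locs), coords, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-9)
        assert res.p <= 0.1  # best achievable with 4! label orders

    def test_null_p_uniform(self, rng):
        """Permutation p-values are uniform when there is no IBD."""
        locs = [f"l{i}" for i in range(6)]
        coords = {l: tuple(rng.uniform(0, 10, 2)) for l in locs}
        ps = []
        for rep in range(200):
            theta = rng.uniform(0.05, 0.4, (6, 6))
            theta = (theta + theta.T) / 2
            np.fill_diagonal(theta, 0)
            res = mantel_ibd(self._pw(theta, locs), coords, n_perm=99,
                             seed=rep)
            ps.append(res.p)
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_theta_one_error(self):
        locs = ["a", "b", "c", "d"]
        theta = np.full((4, 4), 0.5)
        theta[0, 1] = theta[1, 0] = 1.0
        np.fill_diagonal(theta, 0)
        coords = {l: (i, 0) for i, l in enumerate(locs)}
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            mantel_ibd(self._pw(theta, locs), coords)


class TestPcaDapc:
    def test_pct_variance_sums_to_100(self, rng):
        ds = random_dataset(rng, n_samples=15, n_loci=4)
        res = pca(ds)
        assert res.pct_variance.sum() == pytest.approx(100.0)
        assert (res.pct_variance >= 0).all()

    def test_two_pools_separate_on_pc1(self):
        pools = make_ancestral_pools(2, 10, alleles_per_locus=8, f_pool=0.5,
                                     seed=2)
        ds = sample_dataset(pools, [
            PopulationTemplate("a", 25, np.array([1.0, 0.0])),
            PopulationTemplate("b", 25, np.array([0.0, 1.0])),
        ], seed=3)
        res = pca(ds)
        from sklearn.metrics import silhouette_score
        labels = [0] * 25 + [1] * 25
        assert silhouette_score(res.scores[:, :1], labels) > 0.5

    def test_dapc_accuracy_and_membership(self):
        pools = make_ancestral_pools(3, 12, alleles_per_locus=8, f_pool=0.4,
                                     seed=4)
        ds = sample_dataset(pools, [
            PopulationTemplate("a", 20, np.array([1.0, 0, 0])),
            PopulationTemplate("b", 20, np.array([0, 1.0, 0])),
            PopulationTemplate("c", 20, np.array([0, 0, 1.0])),
        ], seed=5)
        res = dapc(ds, ds.localities)
        assert np.allclose(res.membership.sum(axis=1), 1.0)
        acc = np.mean(np.asarray(res.assigned) == np.asarray(ds.localities))
        assert acc >= 0.95

    def test_dapc_permuted_labels_chance(self, rng):
        pools = make_ancestral_pools(2, 8, alleles_per_locus=6, f_pool=0.4,
                                     seed=6)
        ds = sample_dataset(pools, [
            PopulationTemplate("a", 30, np.array([1.0, 0.0])),
            PopulationTemplate("b", 30, np.array([0.0, 1.0])),
        ], seed=7)
        perm = rng.permutation(ds.n_samples)
        shuffled = [ds.localities[i] for i in perm]
        res = dapc(ds, shuffled, n_pcs=5)
        acc = np.mean(np.asarray(res.assigned) == np.asarray(shuffled))
        assert acc < 0.85  # no real signal for arbitrary labels

    def test_single_sample_group_error(self, rng):
        ds = random_dataset(rng, n_samples=6, n_loci=3)
        groups = ["a"] + ["b"] * 5
        with pytest.raises(ValueError):
            dapc(ds, groups)
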