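"""Synthetic SSR genotype generator.

Emulates the statistical structure of a multi-locality, admixed, highly
inbred diploid microsatellite survey so that every downstream analysis
(QC, diversity, F-statistics, admixture clustering) can be exercised and
calibrated without access to real genotypes.

Model
-----
* ``K`` ancestral gene pools share an allele ladder per locus; pool allele
  frequencies are drawn around a common ancestral frequency with a
  Dirichlet whose concentration is ``p * (1 - F_pool) / F_pool`` — the
  classical correlated-allele-frequencies ("F-model") prior, so ``F_pool``
  acts like a per-pool drift/FST parameter.
* Each individual gets an ancestry vector ``q`` (fixed per locality or
  Dirichlet-sampled); each gene copy picks a pool by ``q`` and an allele by
  that pool's frequencies.
* Inbreeding: with probability ``F_target`` the second gene copy duplicates
  the first (within-individual identity), giving an expected heterozygote
  deficit of ``F_target`` — equivalent to partial selfing at equilibrium.
* Null alleles: a hidden allele per locus drawn with the per-locus null
  rate; a carrier heterozygote appears homozygous for its visible allele
  and a double-null cell becomes MISSING (the detection model assumed by
  the Brookfield null-allele estimator).
* Random missingness is applied last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeDataset


@dataclass
class PopulationTemplate:
    """Recipe for one locality's samples."""

    locality: str
    n: int
    ancestry: np.ndarray  # length-K profile summing to 1
    f_target: float = 0.0
    missing_rate: float = 0.0
    null_rate: float = 0.0
    dirichlet_conc: float | None = None  # if set, per-sample q ~ Dir(conc * ancestry)

    def __post_init__(self):
        self.ancestry = np.asarray(self.ancestry, dtype=float)
        if (self.ancestry < 0).any() or abs(self.ancestry.sum() - 1.0) > 1e-9:
            raise ValueError("ancestry must be nonnegative and sum to 1")
        for name in ("f_target", "missing_rate", "null_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass
class AncestralPools:
    """K ancestral gene pools over a shared per-locus allele ladder."""

    freqs: np.ndarray  # (K, n_loci, n_alleles) rows sum to 1
    ladders: np.ndarray  # (n_loci, n_alleles) strictly increasing sizes (bp)
    f_pool: np.ndarray  # per-pool drift parameter

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.ladders = np.asarray(self.ladders, dtype=np.int32)
        if not np.allclose(self.freqs.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("pool frequency vectors must sum to 1")
        if not (np.diff(self.ladders, axis=1) > 0).all():
            raise ValueError("allele ladders must be strictly increasing")

    @property
    def k(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_loci(self) -> int:
        return self.freqs.shape[1]


def make_ancestral_pools(
    K: int,
    n_loci: int,
    alleles_per_locus: int = 10,
    f_pool=0.3,
    seed: int = 0,
    ladder_start: int = 100,
    ladder_step: int = 2,
) -> AncestralPools:
    """Draw ``K`` correlated pool frequency sets over dinucleotide ladders.

    ``f_pool`` may be a scalar or a length-K vector of per-pool drift
    parameters; larger values give pools that are more drifted (fewer
    effective alleles, higher pairwise FST).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if alleles_per_locus < 2:
        raise ValueError("alleles_per_locus must be >= 2")
    f = np.broadcast_to(np.asarray(f_pool, dtype=float), (K,)).copy()
    if ((f <= 0) | (f >= 1)).any():
        raise ValueError("f_pool must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ancestral = rng.dirichlet(np.ones(alleles_per_locus), size=n_loci)  # (L, A)
    freqs = np.empty((K, n_loci, alleles_per_locus))
    for k in range(K):
        conc = ancestral * (1.0 - f[k]) / f[k]
        for l in range(n_loci):
            freqs[k, l] = rng.dirichlet(np.maximum(conc[l], 1e-6))
    ladders = ladder_start + ladder_step * np.arange(alleles_per_locus)
    ladders = np.tile(ladders, (n_loci, 1)).astype(np.int32)
    return AncestralPools(freqs=freqs, ladders=ladders, f_pool=f)


def sample_dataset(
    pools: AncestralPools,
    templates: list,
    seed: int = 0,
    return_truth: bool = False,
):
    """Sample a :class:`GenotypeDataset` from pools + locality templates.

    With ``return_truth`` also returns a dict holding the per-sample true
    ancestry matrix ``q`` (samples x K), the pool frequencies, and the
    per-locality inbreeding targets.
    """
    if not templates:
        raise ValueError("templates must be nonempty")
    master = np.random.default_rng(seed)
    K, L, A = pools.freqs.shape
    sample_ids, localities, blocks, q_rows = [], [], [], []
    for t_i, t in enumerate(templates):
        # one child stream per locality: reproducible regardless of others
        rng = np.random.default_rng(master.integers(2**31))
        n = t.n
        if t.dirichlet_conc is not None:
            q = rng.dirichlet(np.maximum(t.dirichlet_conc * t.ancestry, 1e-9), size=n)
        else:
            q = np.tile(t.ancestry, (n, 1))
        q_rows.append(q)
        # pool of origin per gene copy, then allele index per copy
        z = _sample_categorical(rng, np.repeat(q, 2 * L, axis=0))  # (n*2L,)
        z = z.reshape(n, L, 2)
        li = np.tile(np.arange(L)[None, :, None], (n, 1, 2))
        aidx = _sample_categorical(rng, pools.freqs[z.ravel(), li.ravel()]).reshape(n, L, 2)
        # inbreeding: second copy duplicates the first with prob f_target
        dup = rng.random((n, L)) < t.f_target
        aidx[:, :, 1] = np.where(dup, aidx[:, :, 0], aidx[:, :, 1])
        sizes = np.take_along_axis(
            np.broadcast_to(pools.ladders, (n, L, A)), aidx, axis=2
        ).astype(np.int32)
        # null alleles: each copy independently null with the locus rate
        if t.null_rate > 0:
            is_null = rng.random((n, L, 2)) < t.null_rate
            one_null = is_null.sum(axis=2) == 1
            both_null = is_null.all(axis=2)
            vis = np.where(is_null[:, :, 0], sizes[:, :, 1], sizes[:, :, 0])
            sizes[:, :, 0] = np.where(one_null, vis, sizes[:, :, 0])
            sizes[:, :, 1] = np.where(one_null, vis, sizes[:, :, 1])
            sizes[both_null] = MISSING
        if t.missing_rate > 0:
            drop = rng.random((n, L)) < t.missing_rate
            sizes[drop] = MISSING
        blocks.append(sizes)
        sample_ids.extend(f"{t.locality}_{i:03d}" for i in range(n))
        localities.extend([t.locality] * n)
    calls = np.concatenate(blocks, axis=0)
    ds = GenotypeDataset(sample_ids, list_locus_names(L), calls, localities)
    if not return_truth:
        return ds
    truth = {
        "q": np.vstack(q_rows),
        "pool_freqs": pools.freqs,
        "ladders": pools.ladders,
        "f_target": {t.locality: t.f_target for t in templates},
    }
    return ds, truth


def list_locus_names(L: int) -> list:
    return [f"L{j + 1:02d}" for j in range(L)]


def _sample_categorical(rng, probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw from an (n, K) probability matrix."""
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0 + 1e-12
    u = rng.random((probs.shape[0], 1))
    return (u > cum).sum(axis=1)


# ---------------------------------------------------------------------------
# Study-emulation preset
# ---------------------------------------------------------------------------
# Seven localities, 192 samples, 24 loci, five ancestral gene pools.  Pool
# order: PER-AM, BRA-AM, PER-AND, COL, MEX.  Five localities are pure; the
# Venezuela-Antilles group is an even PER-AM/COL mixture and Central America
# mixes MEX, COL and PER-AM (0.4/0.3/0.3).  The Andes pool is drawn with
# stronger drift so that locality shows the lowest diversity and the largest
# pairwise divergence, while the admixed Mesoamerican locality is the most
# diverse — the qualitative gradient the downstream analyses should recover.

STUDY_POOLS = ["PER-AM", "BRA-AM", "PER-AND", "COL", "MEX"]
STUDY_LOCALITIES = ["MEX", "CenAme", "VEN-ANT", "COL", "BRA-AM", "PER-AM", "PER-AND"]
STUDY_SIZES = {"MEX": 69, "CenAme": 18, "VEN-ANT": 18, "COL": 21,
               "BRA-AM": 37, "PER-AM": 10, "PER-AND": 19}
STUDY_F = {"MEX": 0.52, "CenAme": 0.50, "VEN-ANT": 0.50, "COL": 0.61,
           "BRA-AM": 0.53, "PER-AM": 0.06, "PER-AND": 0.50}
STUDY_COORDS = {"MEX": (20.0, -100.0), "CenAme": (12.0, -85.0),
                "VEN-ANT": (11.0, -67.0), "COL": (4.0, -74.0),
                "BRA-AM": (-3.0, -60.0), "PER-AM": (-5.0, -75.0),
                "PER-AND": (-10.0, -76.0)}
_STUDY_ANCESTRY = {
    # over pools [PER-AM, BRA-AM, PER-AND, COL, MEX]
    "MEX": [0.0, 0.0, 0.0, 0.0, 1.0],
    "CenAme": [0.3, 0.0, 0.0, 0.3, 0.4],
    "VEN-ANT": [0.5, 0.0, 0.0, 0.5, 0.0],
    "COL": [0.0, 0.0, 0.0, 1.0, 0.0],
    "BRA-AM": [0.0, 1.0, 0.0, 0.0, 0.0],
    "PER-AM": [1.0, 0.0, 0.0, 0.0, 0.0],
    "PER-AND": [0.0, 0.0, 1.0, 0.0, 0.0],
}
# Per-pool drift, roughly inversely proportional to each pool's sample mass
# (small, isolated pools are the most drifted), scaled so the multilocus
# F_ST of the emulated survey lands near the study's 0.21.
_STUDY_F_POOL = [0.40, 0.25, 0.45, 0.25, 0.10]
_STUDY_ALLELES = 20  # ladder slots per locus; pooled allele count ~330
_STUDY_MISSING = 0.05


def study_templates() -> list:
    return [
        PopulationTemplate(
            locality=loc,
            n=STUDY_SIZES[loc],
            ancestry=np.array(_STUDY_ANCESTRY[loc]),
            f_target=STUDY_F[loc],
            missing_rate=_STUDY_MISSING,
            null_rate=0.0,
        )
        for loc in STUDY_LOCALITIES
    ]


def study_preset(seed: int = 0):
    """The 192-sample, 24-locus, 7-locality emulation dataset + ground truth.

    Deterministic given ``seed``.  Returns ``(GenotypeDataset, truth)`` where
    ``truth`` carries the per-sample ancestry matrix, pool frequencies,
    ladders, per-locality inbreeding and the pool label order.
    """
    pools = make_ancestral_pools(
        K=5, n_loci=24, alleles_per_locus=_STUDY_ALLELES, f_pool=_STUDY_F_POOL,
        seed=seed,
    )
    ds, truth = sample_dataset(pools, study_templates(), seed=seed + 1, return_truth=True)
    ds.coords.update(STUDY_COORDS)
    truth["pool_labels"] = list(STUDY_POOLS)
    return ds, truth
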