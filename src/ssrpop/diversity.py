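"""Per-locality and pooled diversity statistics for SSR data.

Implements the classical per-locality summary table: number of individuals
(N), allele counts (A), rarefied allelic richness (Ar) and rarefied private
allelic richness (P_Ar, hypergeometric / ADZE-style), observed, expected and
unbiased expected heterozygosity (Ho, He, uHe, with standard errors over
loci) and the fixation index F = 1 - Ho/He.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeDataset


@dataclass
class LocusHet:
    locus: str
    n: int          # complete genotypes
    ho: float
    he: float
    uhe: float


def _complete_pairs(ds: GenotypeDataset, locus: int, sample_idx) -> np.ndarray:
    pairs = ds.calls[sample_idx, locus, :]
    return pairs[pairs[:, 0] != MISSING]


def _locality_indices(ds: GenotypeDataset, locality) -> np.ndarray:
    if locality is None:
        return np.arange(ds.n_samples)
    return ds.samples_of(locality)


def heterozygosities(ds: GenotypeDataset, locality=None):
    """Per-locus (Ho, He, uHe) plus means and standard errors over loci.

    ``locality=None`` pools every sample (the "species" row).  Ho is the
    heterozygote fraction among complete genotypes; He = 1 - sum(p^2);
    uHe = He * 2n/(2n-1).  Loci with no complete genotypes are excluded.
    Returns ``(per_locus, summary)`` where ``summary`` maps each statistic
    to ``(mean, se)`` with se = sd/sqrt(L) over loci.
    """
    si = _locality_indices(ds, locality)
    per_locus = []
    for j in range(ds.n_loci):
        pairs = _complete_pairs(ds, j, si)
        n = len(pairs)
        if n == 0:
            continue
        _, counts = np.unique(pairs.ravel(), return_counts=True)
        p = counts / counts.sum()
        he = 1.0 - float(np.sum(p**2))
        ho = float(np.mean(pairs[:, 0] != pairs[:, 1]))
        uhe = he * 2 * n / (2 * n - 1) if n > 0 else 0.0
        per_locus.append(LocusHet(ds.locus_names[j], n, ho, he, uhe))
    if not per_locus:
        raise ValueError("no locus with complete genotypes")
    summary = {}
    for stat in ("ho", "he", "uhe"):
        vals = np.array([getattr(x, stat) for x in per_locus])
        summary[stat] = (float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))
                         if len(vals) > 1 else 0.0)
    return per_locus, summary


def fixation_index(ds: GenotypeDataset, locality=None):
    """Per-locus F = 1 - Ho/He and its mean over defined loci.

    Loci with He = 0 (monomorphic) are skipped.  Also returns the
    ratio-of-means alternative 1 - mean(Ho)/mean(He) for comparison.
    """
    per_locus, _ = heterozygosities(ds, locality)
    f_by_locus = {x.locus: 1.0 - x.ho / x.he for x in per_locus if x.he > 0}
    if not f_by_locus:
        raise ValueError("all loci monomorphic: F undefined")
    mean_f = float(np.mean(list(f_by_locus.values())))
    ho = np.array([x.ho for x in per_locus if x.he > 0])
    he = np.array([x.he for x in per_locus if x.he > 0])
    ratio_of_means = float(1.0 - ho.mean() / he.mean())
    return f_by_locus, mean_f, ratio_of_means


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def _absence_prob(n_a: np.ndarray, two_n: int, g: int) -> np.ndarray:
    """P(allele with count n_a absent from a size-g subsample of 2n copies)."""
    with np.errstate(invalid="ignore"):
        lp = _log_comb(two_n - n_a, g) - _log_comb(two_n, g)
    return np.where(two_n - n_a < g, 0.0, np.exp(lp))


def rarefied_allelic_richness(ds: GenotypeDataset, locality=None, g: int | None = None):
    """Hypergeometric rarefied allelic richness per locus (and mean).

    Ar(locus) = sum over alleles of P(allele present in a random subsample
    of g gene copies).  ``g`` defaults to the smallest complete-copy count
    over all locality x locus cells of the dataset (the standard
    standardization size).  Returns ``(per_locus_dict, mean, g)``.
    """
    if g is None:
        g = default_rarefaction_size(ds)
    if g < 2:
        raise ValueError("g must be >= 2")
    si = _locality_indices(ds, locality)
    per_locus = {}
    for j in range(ds.n_loci):
        pairs = _complete_pairs(ds, j, si)
        if len(pairs) == 0:
            continue
        two_n = 2 * len(pairs)
        if g > two_n:
            raise ValueError(f"g={g} exceeds {two_n} copies at locus {ds.locus_names[j]}")
        _, counts = np.unique(pairs.ravel(), return_counts=True)
        ar = float(np.sum(1.0 - _absence_prob(counts, two_n, g)))
        per_locus[ds.locus_names[j]] = ar
    mean = float(np.mean(list(per_locus.values())))
    return per_locus, mean, g


def default_rarefaction_size(ds: GenotypeDataset) -> int:
    """Smallest number of complete gene copies over locality x locus cells."""
    best = None
    for loc in ds.locality_order():
        si = ds.samples_of(loc)
        for j in range(ds.n_loci):
            n = len(_complete_pairs(ds, j, si))
            two_n = 2 * n
            if two_n > 0:
                best = two_n if best is None else min(best, two_n)
    if best is None or best < 2:
        raise ValueError("cannot determine a rarefaction size")
    return best


def private_allelic_richness(ds: GenotypeDataset, g: int | None = None):
    """ADZE-style rarefied private allelic richness per locality.

    For locality j, P_Ar is the expected number of alleles present in a
    size-g subsample from j and absent from independent size-g subsamples
    of every other locality, summed over loci and alleles, averaged over
    loci.  Returns ``(per_locality_mean, per_locality_per_locus, g)``.
    """
    locs = ds.locality_order()
    if len(locs) < 2:
        raise ValueError("need >= 2 localities for private allele rarefaction")
    if g is None:
        g = default_rarefaction_size(ds)
    per_loc_locus: dict = {loc: {} for loc in locs}
    for j in range(ds.n_loci):
        # allele counts per locality
        counts = {}
        alleles = set()
        for loc in locs:
            c = ds.allele_counts(j, ds.samples_of(loc))
            counts[loc] = c
            alleles.update(c)
        alleles = sorted(alleles)
        two_n = {loc: sum(counts[loc].values()) for loc in locs}
        for loc in locs:
            if two_n[loc] == 0:
                continue
            if g > two_n[loc]:
                raise ValueError(
                    f"g={g} exceeds {two_n[loc]} copies in {loc} at {ds.locus_names[j]}")
        total = {loc: 0.0 for loc in locs}
        for a in alleles:
            pres = {}
            absn = {}
            for loc in locs:
                na = counts[loc].get(a, 0)
                q = float(_absence_prob(np.array([na]), two_n[loc], g)[0])
                absn[loc] = q
                pres[loc] = 1.0 - q
            for loc in locs:
                others = np.prod([absn[o] for o in locs if o != loc])
                total[loc] += pres[loc] * float(others)
        for loc in locs:
            per_loc_locus[loc][ds.locus_names[j]] = total[loc]
    per_loc_mean = {loc: float(np.mean(list(v.values())))
                    for loc, v in per_loc_locus.items()}
    return per_loc_mean, per_loc_locus, g


def allele_count(ds: GenotypeDataset, locality=None) -> int:
    """Total distinct alleles summed over loci (complete genotypes only)."""
    si = _locality_indices(ds, locality)
    total = 0
    for j in range(ds.n_loci):
        pairs = _complete_pairs(ds, j, si)
        if len(pairs):
            total += len(np.unique(pairs.ravel()))
    return total


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

def diversity_table(ds: GenotypeDataset, g: int | None = None) -> pd.DataFrame:
    """One row per locality plus a pooled "species" row.

    Columns: locality, N, A, Ar, P_Ar, Ho, Ho_se, He, He_se, uHe, uHe_se, F.
    The pooled row ignores locality labels (P_Ar undefined there).
    """
    if g is None:
        g = default_rarefaction_size(ds)
    p_ar, _, _ = private_allelic_richness(ds, g=g)
    rows = []
    for loc in [None] + ds.locality_order():
        si = _locality_indices(ds, loc)
        _, summary = heterozygosities(ds, loc)
        _, mean_f, _ = fixation_index(ds, loc)
        _, ar, _ = rarefied_allelic_richness(ds, loc, g=g)
        rows.append({
            "locality": "species" if loc is None else loc,
            "N": len(si),
            "A": allele_count(ds, loc),
            "Ar": ar,
            "P_Ar": float("nan") if loc is None else p_ar[loc],
            "Ho": summary["ho"][0], "Ho_se": summary["ho"][1],
            "He": summary["he"][0], "He_se": summary["he"][1],
            "uHe": summary["uhe"][0], "uHe_se": summary["uhe"][1],
            "F": mean_f,
        })
    return pd.DataFrame(rows)
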