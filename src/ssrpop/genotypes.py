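"""Diploid codominant genotype data model and file I/O.

The central container is :class:`GenotypeDataset`: a samples x loci table of
unordered diploid allele-size pairs (microsatellite fragment lengths in base
pairs), with a locality label per sample and optional locality coordinates.
Readers are provided for GenePop 4.x, STRUCTURE (1- or 2-row) and a simple
CSV dialect; writers re-emit files the corresponding readers accept.

A cell is either a complete pair or wholly missing: half-called cells (one
allele scored, one missing) are coerced to missing at ingest because every
downstream estimator assumes complete diploid genotypes.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field

import numpy as np

#: Sentinel allele value marking a missing cell (both slots).
MISSING = -1


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates its format contract."""


class GenotypeEncodeError(ValueError):
    """Raised when a dataset cannot be represented in the requested format."""


@dataclass
class GenotypeDataset:
    """Diploid SSR genotypes for a set of samples at a set of loci.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``calls``.
    locus_names : list of str
        Unique locus identifiers, one per column of ``calls``.
    calls : ndarray of shape (n_samples, n_loci, 2), int
        Allele sizes in base pairs; a missing cell holds ``MISSING`` in both
        slots.  Pairs are stored sorted (unordered genotypes).
    localities : list of str
        Locality label per sample.
    coords : dict, optional
        Locality -> (latitude, longitude) in decimal degrees.
    """

    sample_ids: list
    locus_names: list
    calls: np.ndarray
    localities: list
    coords: dict = field(default_factory=dict)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValueError("calls must have shape (n_samples, n_loci, 2)")
        if self.calls.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match calls")
        if self.calls.shape[1] != len(self.locus_names):
            raise ValueError("locus_names length does not match calls")
        if len(self.localities) != len(self.sample_ids):
            raise ValueError("localities length does not match sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError("duplicate locus names")
        self.calls = _normalize_calls(self.calls)
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing cell survived normalization")
        valid = self.calls[self.calls != MISSING]
        if valid.size and (valid <= 0).any():
            raise ValueError("allele sizes must be positive integers")
        unknown = set(self.coords) - set(self.localities)
        if unknown:
            raise ValueError(f"coords reference unknown localities: {sorted(unknown)}")

    # -- basic shape ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci) mask of missing cells."""
        return self.calls[:, :, 0] == MISSING

    def locality_order(self) -> list:
        """Locality labels in order of first appearance."""
        seen: dict = {}
        for loc in self.localities:
            seen.setdefault(loc, None)
        return list(seen)

    def samples_of(self, locality) -> np.ndarray:
        """Row indices of the samples belonging to ``locality``."""
        return np.flatnonzero(np.asarray(self.localities, dtype=object) == locality)

    # -- subsetting ----------------------------------------------------
    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeDataset":
        """Return a new dataset restricted to the given sample/locus indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        localities = [self.localities[i] for i in si]
        coords = {k: v for k, v in self.coords.items() if k in set(localities)}
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in si],
            locus_names=[self.locus_names[j] for j in li],
            calls=self.calls[np.ix_(si, li)],
            localities=localities,
            coords=coords,
        )

    # -- allele bookkeeping -------------------------------------------
    def allele_counts(self, locus: int, sample_idx=None) -> dict:
        """Allele -> gene-copy count at ``locus`` among complete genotypes."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        col = self.calls[si, locus, :]
        col = col[col[:, 0] != MISSING]
        vals, counts = np.unique(col.ravel(), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def __eq__(self, other):
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_names == other.locus_names
            and np.array_equal(self.calls, other.calls)
            and self.localities == other.localities
            and self.coords == other.coords
        )


def _normalize_calls(calls: np.ndarray) -> np.ndarray:
    """Coerce half-missing cells to fully missing and sort each pair."""
    calls = calls.copy()
    half = (calls == MISSING).sum(axis=2) == 1
    calls[half] = MISSING
    complete = calls[:, :, 0] != MISSING
    pair = calls[complete]
    calls[complete] = np.sort(pair, axis=1)
    return calls


@dataclass
class MissingnessReport:
    """Result of :func:`filter_missing`: what was removed and why."""

    threshold: float
    sample_missing: dict
    locus_missing: dict
    removed_samples: list
    removed_loci: list


def filter_missing(ds: GenotypeDataset, threshold: float = 0.40):
    """Drop samples, then loci, whose missing fraction exceeds ``threshold``.

    Samples are removed first; locus missingness is then recomputed on the
    retained samples before loci are removed, mirroring the usual
    remove-samples-then-discard-locus order of SSR QC.  The sample/locus
    passes repeat until nothing more exceeds the threshold, so the filter
    is idempotent by construction.

    Returns ``(filtered_dataset, MissingnessReport)``.  Raises ``ValueError``
    if every locus would be removed.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    sfrac0 = ds.missing_mask.mean(axis=1)
    lfrac0 = ds.missing_mask.mean(axis=0)
    keep_s = np.arange(ds.n_samples)
    keep_l = np.arange(ds.n_loci)
    removed_samples: list = []
    removed_loci: list = []
    while True:
        miss = ds.missing_mask[np.ix_(keep_s, keep_l)]
        if keep_l.size == 0:
            raise ValueError("missingness filter removed every locus")
        sfrac = miss.mean(axis=1) if keep_l.size else np.ones(keep_s.size)
        bad_s = sfrac > threshold
        if bad_s.any():
            removed_samples += [ds.sample_ids[i] for i in keep_s[bad_s]]
            keep_s = keep_s[~bad_s]
            continue
        lfrac = (ds.missing_mask[np.ix_(keep_s, keep_l)].mean(axis=0)
                 if keep_s.size else np.ones(keep_l.size))
        bad_l = lfrac > threshold
        if bad_l.any():
            removed_loci += [ds.locus_names[j] for j in keep_l[bad_l]]
            keep_l = keep_l[~bad_l]
            continue
        break
    report = MissingnessReport(
        threshold=threshold,
        sample_missing={ds.sample_ids[i]: float(sfrac0[i]) for i in range(ds.n_samples)},
        locus_missing={ds.locus_names[j]: float(lfrac0[j]) for j in range(ds.n_loci)},
        removed_samples=removed_samples,
        removed_loci=removed_loci,
    )
    return ds.subset(keep_s, keep_l), report


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def read_genepop(path) -> GenotypeDataset:
    """Read a GenePop 4.x file (2- or 3-digit allele coding, 0 = missing).

    Each ``Pop`` block becomes one locality, labelled ``pop1``, ``pop2``, ...
    in file order (GenePop carries no locality names).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise GenotypeParseError("empty GenePop file")
    # locus names: either one per line or comma-separated on one line
    locus_names: list = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i >= len(lines) and not locus_names:
        raise GenotypeParseError("no locus names / no Pop line found")
    sample_ids, localities, rows = [], [], []
    pop_no = 0
    while i < len(lines):
        if lines[i].strip().lower() != "pop":
            raise GenotypeParseError(f"expected 'Pop' at line {i + 1}")
        pop_no += 1
        i += 1
        while i < len(lines) and lines[i].strip().lower() != "pop":
            line = lines[i].strip()
            i += 1
            if not line:
                continue
            if "," not in line:
                raise GenotypeParseError(f"missing ',' separator at line {i}")
            name, geno = line.split(",", 1)
            codes = geno.split()
            if len(codes) != len(locus_names):
                raise GenotypeParseError(
                    f"line {i}: expected {len(locus_names)} loci, got {len(codes)}"
                )
            row = []
            for code in codes:
                if len(code) not in (4, 6) or not code.isdigit():
                    raise GenotypeParseError(f"line {i}: bad allele code '{code}'")
                w = len(code) // 2
                a, b = int(code[:w]), int(code[w:])
                row.append((a if a else MISSING, b if b else MISSING))
            sample_ids.append(name.strip())
            localities.append(f"pop{pop_no}")
            rows.append(row)
    calls = np.array(rows, dtype=np.int32) if rows else np.empty((0, len(locus_names), 2), np.int32)
    return GenotypeDataset(sample_ids, locus_names, calls, localities)


def write_genepop(ds: GenotypeDataset, path, title: str = "ssrpop export") -> None:
    """Write GenePop; 3-digit coding if any allele exceeds 99, else 2-digit."""
    valid = ds.calls[ds.calls != MISSING]
    amax = int(valid.max()) if valid.size else 0
    if amax > 999:
        raise GenotypeEncodeError(f"allele size {amax} not encodable in 3 digits")
    width = 3 if amax > 99 else 2
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in ds.locus_names:
            fh.write(name + "\n")
        for loc in ds.locality_order():
            fh.write("Pop\n")
            for i in ds.samples_of(loc):
                codes = []
                for j in range(ds.n_loci):
                    a, b = ds.calls[i, j]
                    a = 0 if a == MISSING else int(a)
                    b = 0 if b == MISSING else int(b)
                    codes.append(f"{a:0{width}d}{b:0{width}d}")
                fh.write(f"{ds.sample_ids[i]} , " + " ".join(codes) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE
# ---------------------------------------------------------------------------

def read_structure(path, rows_per_individual: int = 2, popinfo: bool = True) -> GenotypeDataset:
    """Read a STRUCTURE input file (-9 = missing).

    ``rows_per_individual=2``: each individual occupies two rows, one allele
    per locus per row.  ``rows_per_individual=1``: one row with 2 x n_loci
    allele columns.  The first line is a whitespace-separated locus-name
    header; with ``popinfo`` the column after the sample id is the locality.
    """
    if rows_per_individual not in (1, 2):
        raise ValueError("rows_per_individual must be 1 or 2")
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeParseError("empty STRUCTURE file")
    locus_names = lines[0]
    body = lines[1:]
    base = 2 if popinfo else 1
    sample_ids, localities, rows = [], [], []
    if rows_per_individual == 2:
        if len(body) % 2:
            raise GenotypeParseError("odd number of allele rows in 2-row mode")
        for r in range(0, len(body), 2):
            top, bot = body[r], body[r + 1]
            if top[0] != bot[0]:
                raise GenotypeParseError(
                    f"row pair {r // 2 + 1}: sample ids differ ({top[0]!r} vs {bot[0]!r})"
                )
            if len(top) != base + len(locus_names) or len(bot) != len(top):
                raise GenotypeParseError(f"row pair {r // 2 + 1}: wrong column count")
            sample_ids.append(top[0])
            localities.append(top[1] if popinfo else "pop1")
            row = []
            for j in range(len(locus_names)):
                a, b = int(top[base + j]), int(bot[base + j])
                row.append((MISSING if a == -9 else a, MISSING if b == -9 else b))
            rows.append(row)
    else:
        for r, rec in enumerate(body):
            if len(rec) != base + 2 * len(locus_names):
                raise GenotypeParseError(f"row {r + 1}: wrong column count")
            sample_ids.append(rec[0])
            localities.append(rec[1] if popinfo else "pop1")
            row = []
            for j in range(len(locus_names)):
                a, b = int(rec[base + 2 * j]), int(rec[base + 2 * j + 1])
                row.append((MISSING if a == -9 else a, MISSING if b == -9 else b))
            rows.append(row)
    calls = np.array(rows, dtype=np.int32) if rows else np.empty((0, len(locus_names), 2), np.int32)
    return GenotypeDataset(sample_ids, locus_names, calls, localities)


def write_structure(ds: GenotypeDataset, path, rows_per_individual: int = 2) -> None:
    """Write STRUCTURE input; localities encoded as 1-based integers."""
    loc_code = {loc: k + 1 for k, loc in enumerate(ds.locality_order())}
    with open(path, "w") as fh:
        fh.write(" ".join(ds.locus_names) + "\n")
        for i, sid in enumerate(ds.sample_ids):
            pop = loc_code[ds.localities[i]]
            a = [(-9 if v == MISSING else int(v)) for v in ds.calls[i, :, 0]]
            b = [(-9 if v == MISSING else int(v)) for v in ds.calls[i, :, 1]]
            if rows_per_individual == 2:
                fh.write(f"{sid} {pop} " + " ".join(map(str, a)) + "\n")
                fh.write(f"{sid} {pop} " + " ".join(map(str, b)) + "\n")
            else:
                inter = [str(x) for pair in zip(a, b) for x in pair]
                fh.write(f"{sid} {pop} " + " ".join(inter) + "\n")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------
# header: sample,locality,lat,lon,<locus>_1,<locus>_2,...  missing = empty field

def read_csv(path) -> GenotypeDataset:
    """Read the package CSV dialect (full fidelity incl. coordinates)."""
    with open(path, newline="") as fh:
        reader = _csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise GenotypeParseError("empty CSV file")
        if header[:4] != ["sample", "locality", "lat", "lon"]:
            raise GenotypeParseError("CSV header must start with sample,locality,lat,lon")
        allele_cols = header[4:]
        if len(allele_cols) % 2:
            raise GenotypeParseError("odd number of allele columns")
        locus_names = []
        for j in range(0, len(allele_cols), 2):
            c1, c2 = allele_cols[j], allele_cols[j + 1]
            if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
                raise GenotypeParseError(f"allele columns {c1!r},{c2!r} not a <locus>_1/_2 pair")
            locus_names.append(c1[:-2])
        sample_ids, localities, rows, coords = [], [], [], {}
        for rec in reader:
            if not rec or not any(rec):
                continue
            if len(rec) != len(header):
                raise GenotypeParseError(f"row for {rec[0]!r}: wrong field count")
            sample_ids.append(rec[0])
            localities.append(rec[1])
            if rec[2] and rec[3]:
                coords[rec[1]] = (float(rec[2]), float(rec[3]))
            row = []
            for j in range(len(locus_names)):
                a, b = rec[4 + 2 * j], rec[5 + 2 * j]
                row.append((int(a) if a else MISSING, int(b) if b else MISSING))
            rows.append(row)
    calls = np.array(rows, dtype=np.int32) if rows else np.empty((0, len(locus_names), 2), np.int32)
    return GenotypeDataset(sample_ids, locus_names, calls, localities, coords)


def write_csv(ds: GenotypeDataset, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = _csv.writer(fh)
        header = ["sample", "locality", "lat", "lon"]
        for name in ds.locus_names:
            header += [f"{name}_1", f"{name}_2"]
        writer.writerow(header)
        for i, sid in enumerate(ds.sample_ids):
            loc = ds.localities[i]
            lat, lon = ds.coords.get(loc, ("", ""))
            rec = [sid, loc, lat, lon]
            for j in range(ds.n_loci):
                a, b = ds.calls[i, j]
                rec += ["" if a == MISSING else int(a), "" if b == MISSING else int(b)]
            writer.writerow(rec)
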