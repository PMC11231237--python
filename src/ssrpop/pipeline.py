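"""End-to-end analysis pipeline: QC -> diversity -> differentiation ->
admixture -> ABC scenario choice, from a single config.

The config is a YAML mapping (see :class:`PipelineConfig`); each stage
writes versioned outputs under the output directory, and a manifest records
the package version, a config hash, the master seed, and per-stage wall
times.  Deterministic stages are byte-identical across reruns of the same
config + seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import GenotypeDataset, filter_missing, read_csv, read_genepop, read_structure
from . import qc as _qc
from . import diversity as _div
from . import differentiation as _diff
from . import admixture as _adm
from . import scenarios as _scn
from .simulate import study_preset


@dataclass
class PipelineConfig:
    input_path: str | None = None       # None -> built-in study preset
    input_format: str = "csv"           # csv | genepop | structure
    missing_threshold: float = 0.40
    n_perm: int = 999
    n_boot: int = 10000
    hwe_perm: int = 1000
    k_min: int = 1
    k_max: int = 8
    admixture_reps: int = 3
    admixture_iters: int = 600
    admixture_burnin: int = 200
    abc_enabled: bool = True
    abc_sims: int = 2000
    abc_trees: int = 500
    abc_loci: int = 10
    abc_samples_per_deme: int = 5
    abc_pods: int = 100
    abc_tight_priors: bool = True
    seed: int = 0
    out_dir: str = "ssrpop_out"
    stages: tuple = ("qc", "diversity", "differentiation", "admixture", "abc")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_input(cfg: PipelineConfig) -> GenotypeDataset:
    if cfg.input_path is None:
        ds, _ = study_preset(cfg.seed)
        return ds
    readers = {"csv": read_csv, "genepop": read_genepop, "structure": read_structure}
    if cfg.input_format not in readers:
        raise ValueError(f"unknown input format {cfg.input_format!r}")
    return readers[cfg.input_format](cfg.input_path)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dict.

    Stage outputs land under ``out_dir/<stage>/``; the manifest is written
    to ``out_dir/manifest.json`` and aggregates warnings and timings.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "seed": cfg.seed,
        "stages": {},
        "warnings": [],
    }
    rng = np.random.default_rng(cfg.seed)
    ds = _load_input(cfg)
    ds, report = filter_missing(ds, cfg.missing_threshold)
    (out / "qc").mkdir(exist_ok=True)
    with open(out / "qc" / "missingness.json", "w") as fh:
        json.dump({"threshold": report.threshold,
                   "removed_samples": report.removed_samples,
                   "removed_loci": report.removed_loci}, fh, indent=1)

    if "qc" in cfg.stages:
        t0 = time.perf_counter()
        rows = []
        for loc in ds.locality_order():
            for j in range(ds.n_loci):
                try:
                    est = _qc.brookfield_null(ds, j, loc)
                except ValueError:
                    continue
                if est is not None:
                    rows.append({"locus": est.locus, "locality": est.locality,
                                 "r": est.r, "r_raw": est.r_raw, "n": est.n})
        pd.DataFrame(rows).to_csv(out / "qc" / "null_alleles.csv", index=False)
        hwe, locus_family = _qc.hwe_table(ds, n_perm=cfg.hwe_perm,
                                          seed=int(rng.integers(2**31)))
        pd.DataFrame([{"locus": r.locus, "locality": r.locality, "chi2": r.chi2,
                       "p_mc": r.p_mc, "p_adj": r.p_adj, "n": r.n}
                      for r in hwe]).to_csv(out / "qc" / "hwe.csv", index=False)
        with open(out / "qc" / "hwe_locus_families.json", "w") as fh:
            json.dump(locus_family, fh, indent=1)
        ld = _qc.index_of_association(ds, None, n_perm=min(cfg.n_perm, 199),
                                      seed=int(rng.integers(2**31)))
        curve = _qc.genotype_accumulation(ds, n_resamples=100,
                                         seed=int(rng.integers(2**31)))
        with open(out / "qc" / "ld_and_accumulation.json", "w") as fh:
            json.dump({"rbar_d": ld.rbar_d, "p": ld.p_perm, "n_perm": ld.n_perm,
                       "accumulation_medians": curve.medians.tolist(),
                       "plateau": curve.plateau,
                       "loci_for_full_discrimination":
                           _qc.loci_for_full_discrimination(curve)}, fh, indent=1)
        manifest["stages"]["qc"] = {"seconds": round(time.perf_counter() - t0, 2)}

    if "diversity" in cfg.stages:
        t0 = time.perf_counter()
        (out / "diversity").mkdir(exist_ok=True)
        table = _div.diversity_table(ds)
        table.to_csv(out / "diversity" / "diversity.csv", index=False)
        manifest["stages"]["diversity"] = {"seconds": round(time.perf_counter() - t0, 2)}

    if "differentiation" in cfg.stages:
        t0 = time.perf_counter()
        d = out / "differentiation"
        d.mkdir(exist_ok=True)
        fh_stats = _diff.wc_f_statistics(ds, n_boot=cfg.n_boot,
                                         seed=int(rng.integers(2**31)))
        with open(d / "f_statistics.json", "w") as fh:
            json.dump({"F_IS": fh_stats.f_is, "F_IT": fh_stats.f_it,
                       "F_ST": fh_stats.f_st, "ci": fh_stats.ci,
                       "n_boot": fh_stats.n_boot}, fh, indent=1)
        pw = _diff.pairwise_fst(ds, n_boot=min(cfg.n_boot, 999),
                                seed=int(rng.integers(2**31)))
        pd.DataFrame(pw.theta, index=pw.localities,
                     columns=pw.localities).to_csv(d / "pairwise_fst.csv")
        am = _diff.amova(ds, n_perm=cfg.n_perm, seed=int(rng.integers(2**31)))
        pd.DataFrame(am.rows).to_csv(d / "amova.csv", index=False)
        if ds.coords:
            mt = _diff.mantel_ibd(pw, ds.coords, n_perm=cfg.n_perm,
                                  seed=int(rng.integers(2**31)))
            with open(d / "mantel.json", "w") as fh:
                json.dump({"r": mt.r, "r_squared": mt.r_squared, "p": mt.p,
                           "n_perm": mt.n_perm}, fh, indent=1)
        else:
            manifest["warnings"].append("no coordinates: Mantel test skipped")
        pca_res = _diff.pca(ds)
        np.savetxt(d / "pca_scores.csv",
                   np.column_stack([pca_res.scores[:, :2]]), delimiter=",")
        dapc_res = _diff.dapc(ds, ds.localities)
        pd.DataFrame(dapc_res.membership, index=ds.sample_ids,
                     columns=dapc_res.groups).to_csv(d / "dapc_membership.csv")
        _scatter_plot(pca_res, ds, d / "pca.png")
        manifest["stages"]["differentiation"] = {
            "seconds": round(time.perf_counter() - t0, 2),
            "F_ST": fh_stats.f_st, "F_IS": fh_stats.f_is, "F_IT": fh_stats.f_it}
    if "admixture" in cfg.stages:
        t0 = time.perf_counter()
        d = out / "admixture"
        d.mkdir(exist_ok=True)
        runs = []
        for K in range(cfg.k_min, cfg.k_max + 1):
            for rep in range(cfg.admixture_reps):
                runs.append(_adm.run_admixture(
                    ds, K, iters=cfg.admixture_iters, burnin=cfg.admixture_burnin,
                    seed=int(rng.integers(2**31))))
        sel = _adm.select_k(runs)
        with open(d / "k_selection.json", "w") as fh:
            json.dump({"mean_lnp": sel.mean_lnp, "sd_lnp": sel.sd_lnp,
                       "delta_k": sel.delta_k, "best_k_delta": sel.best_k_delta,
                       "best_k_lnp": sel.best_k_lnp}, fh, indent=1, default=float)
        best_k = sel.best_k_delta or sel.best_k_lnp
        for K in range(cfg.k_min, cfg.k_max + 1):
            k_runs = [r for r in runs if r.k == K]
            consensus = (_adm.align_runs(k_runs)[1] if len(k_runs) > 1
                         else k_runs[0].q)
            qdf = pd.DataFrame(consensus, index=ds.sample_ids,
                               columns=[f"cluster{i + 1}" for i in range(K)])
            qdf.insert(0, "locality", ds.localities)
            qdf.to_csv(d / f"consensus_Q_K{K}.csv")
            if K == best_k:
                _bar_plot(consensus, ds, d / f"admixture_K{K}.png")
        manifest["stages"]["admixture"] = {
            "seconds": round(time.perf_counter() - t0, 2), "best_k": int(best_k)}

    if "abc" in cfg.stages and cfg.abc_enabled:
        t0 = time.perf_counter()
        d = out / "abc"
        d.mkdir(exist_ok=True)
        scns = _scn.default_scenarios(tight_priors=cfg.abc_tight_priors)
        mm = _scn.MutationModel()
        sizes = {dm: cfg.abc_samples_per_deme for dm in _scn.DEMES}
        ref = _scn.build_reference_table(scns, mm, cfg.abc_sims, sizes,
                                         cfg.abc_loci, seed=int(rng.integers(2**31)))
        pd.DataFrame(ref.stats, columns=ref.stat_names).assign(
            scenario=ref.scenario_ids).to_csv(d / "reference_table.csv", index=False)
        # observed vector: a pseudo-observation from the best-supported
        # topology (there is no real deposit to read)
        rng_obs = np.random.default_rng(int(rng.integers(2**31)))
        sc2 = next(s for s in scns if s.id == 2)
        obs_ds = _scn.simulate_coalescent(
            sc2, sc2.draw_params(rng_obs), mm.draw(cfg.abc_loci, rng_obs),
            sizes, cfg.abc_loci, seed=int(rng_obs.integers(2**31)))
        obs = _scn.summary_stats(obs_ds)
        cls = _scn.classify_scenario(ref, obs, n_trees=cfg.abc_trees,
                                     seed=int(rng.integers(2**31)))
        pods = _scn.pod_error_rates(
            ref, scns, mm, sizes, cfg.abc_loci,
            n_pods_per_scenario=cfg.abc_pods, n_trees=cfg.abc_trees,
            seed=int(rng.integers(2**31)))
        with open(d / "classification.json", "w") as fh:
            json.dump({"chosen": cls.chosen, "votes": cls.votes,
                       "posterior_prob": cls.posterior_prob,
                       "posterior_method": cls.posterior_method,
                       "oob_error": cls.oob_error,
                       "pod_error_rates": pods}, fh, indent=1, default=float)
        manifest["stages"]["abc"] = {"seconds": round(time.perf_counter() - t0, 2),
                                     "chosen_scenario": cls.chosen}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _scatter_plot(pca_res, ds, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for loc in ds.locality_order():
        si = ds.samples_of(loc)
        ax.scatter(pca_res.scores[si, 0], pca_res.scores[si, 1], s=12, label=loc)
    ax.set_xlabel(f"PC1 ({pca_res.pct_variance[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pca_res.pct_variance[1]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _bar_plot(q, ds, path, locality_order=None):
    """Stacked ancestry bars, samples grouped by locality."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = locality_order or ds.locality_order()
    idx = np.concatenate([ds.samples_of(loc) for loc in order])
    qq = q[idx]
    fig, ax = plt.subplots(figsize=(10, 3))
    bottom = np.zeros(len(idx))
    for k in range(qq.shape[1]):
        ax.bar(np.arange(len(idx)), qq[:, k], bottom=bottom, width=1.0)
        bottom += qq[:, k]
    ax.set_xlim(-0.5, len(idx) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
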