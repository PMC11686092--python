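"""End-to-end orchestration from a config file.

Stages run in dependency order:

    simulate/ingest -> gl -> filter -> {structure, diversity, differentiation}
        -> {scan, localpca, linkage_dosage} -> mito -> report

Every stochastic stage draws from a substream derived from the single run
seed, so a fixed seed reproduces the whole output directory byte for byte.
A ``manifest.json`` records parameters, seeds and SHA-256 hashes of every
artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import stage_seed
from .glcore import (
    BASE_INDEX,
    GLMatrix,
    gl_from_counts,
    read_beagle,
    read_counts_tsv,
    write_beagle,
)
from .filters import SiteFilterConfig, apply_filters, call_snps, estimate_maf_em
from .simdata import SimConfig, read_mito_counts, simulate_dataset
from . import differentiation, diversity, linkage_dosage, localpca, mito, scan, structure

__all__ = ["PipelineConfig", "PipelineError", "run", "demo_config"]

_FLOAT_FMT = "%.6g"
STAGE_ORDER = [
    "simulate", "gl", "filter", "structure", "diversity", "differentiation",
    "scan", "localpca", "linkage_dosage", "mito", "report",
]
_DEPENDS = {
    "gl": ["simulate"],
    "filter": ["gl"],
    "structure": ["filter"],
    "diversity": ["filter"],
    "differentiation": ["filter"],
    "scan": ["filter"],
    "localpca": ["filter"],
    "linkage_dosage": ["scan"],
    "report": [],
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Run configuration; defaults follow the source study's settings."""

    seed: int
    outdir: str
    simdata: dict[str, Any] | None = None  # SimConfig fields
    inputs: dict[str, str] | None = None  # beagle/popmap/counts/mito_counts paths
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    filters: dict[str, Any] = field(default_factory=dict)
    structure: dict[str, Any] = field(
        default_factory=lambda: {
            "k_range": [1, 8], "n_restarts": 10, "subsample_to": 16,
            "admix_max_sites": None,
        }
    )
    diversity: dict[str, Any] = field(
        default_factory=lambda: {"window_size": 5000, "step": 1000}
    )
    scan: dict[str, Any] = field(
        default_factory=lambda: {
            "xi": 2.0, "alpha": 0.01, "n_perm": 1000,
            "maf_min": 0.05, "snp_p_max": 1e-10,
        }
    )
    linkage: dict[str, Any] = field(
        default_factory=lambda: {"max_dist": 100_000, "subsample_every": 10}
    )
    mito: dict[str, Any] = field(
        default_factory=lambda: {"min_depth": 4, "min_maf": 0.75}
    )

    def __post_init__(self) -> None:
        if self.simdata is None and self.inputs is None:
            raise PipelineError("config needs either a simdata block or inputs")
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        if self.inputs is not None:
            for key, p in self.inputs.items():
                if not Path(p).exists():
                    raise PipelineError(f"input path for {key!r} missing: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def demo_config(outdir: str, seed: int = 1) -> PipelineConfig:
    """The one-command synthetic demo: 5 pops x 15 individuals x 20,000 SNPs.

    Heavy stages are scaled for a single CPU: admixture runs K = 1..3 with
    two restarts on a 4,000-site subsample, and scan permutations are 200 per
    chromosome.
    """
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        simdata={
            "n_pops": 5,
            "pop_sizes": (15, 15, 15, 15, 15),
            "pop_names": ("NorChu", "EBS", "GOA", "SEAK", "AIs"),
            "n_sites": 20_000,
            "chrom_lengths": {f"chr{i}": 1_000_000 for i in range(1, 11)},
            "depth_lambda": 2.0,
            "sweep_region": ("chr10", 400_000, 500_000, (0.0, 0.0, 0.0, 0.8, 0.0)),
            "seed": seed,
        },
        filters={"min_total_depth": 50, "max_total_depth": 1500},
        structure={"k_range": [1, 3], "n_restarts": 2, "subsample_to": 16,
                   "admix_max_sites": 2000, "max_iter": 300},
        scan={"xi": 2.0, "alpha": 0.01, "n_perm": 200,
              "maf_min": 0.05, "snp_p_max": 1e-10},
    )


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n",
              float_format=_FLOAT_FMT)


def _require(state: dict, key: str, stage: str, needed_by: str) -> Any:
    if key not in state:
        raise PipelineError(
            f"stage {needed_by!r} requires {key!r} from stage {stage!r}, "
            f"which did not run (toggled off or failed)"
        )
    return state[key]


def run(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict[str, Any] = {}
    stages = [s for s in STAGE_ORDER if s in config.stages]

    if "simulate" in stages and config.simdata is not None:
        sim_cfg = SimConfig.from_dict(
            {**config.simdata, "seed": config.simdata.get("seed", config.seed)}
        )
        simdir = out / "simulated"
        gl, mito_counts, truth = simulate_dataset(sim_cfg, simdir)
        state["sim_config"] = sim_cfg
        state["gl_raw"] = gl
        state["mito_counts"] = mito_counts
        state["mito_individuals"] = sim_cfg.individuals()
        state["truth"] = truth
        state["counts_path"] = simdir / "counts.tsv"
        state["chrom_lengths"] = dict(sim_cfg.chrom_lengths)
    elif config.inputs is not None:
        inputs = config.inputs
        popmap = pd.read_csv(inputs["popmap"], sep="\t") if "popmap" in inputs else None
        if "beagle" in inputs:
            state["gl_raw"] = read_beagle(inputs["beagle"], popmap)
        elif "counts" in inputs:
            sites, individuals, counts = read_counts_tsv(inputs["counts"])
            if popmap is not None:
                individuals = popmap
            raise PipelineError(
                "counts-only ingestion requires major/minor alleles; provide "
                "a beagle file (the gl stage writes one from simulated counts)"
            )
        if "mito_counts" in inputs:
            ind, counts = read_mito_counts(inputs["mito_counts"])
            state["mito_counts"] = counts
            state["mito_individuals"] = (
                popmap if popmap is not None else ind.assign(pop="unknown")
            )
        state["counts_path"] = inputs.get("counts")

    if "gl" in stages:
        gl = _require(state, "gl_raw", "simulate", "gl")
        # Simulated data arrives GL-ready; re-emit the canonical Beagle file.
        write_beagle(gl, out / "genolike.beagle.tsv")

    if "filter" in stages:
        gl = _require(state, "gl_raw", "gl", "filter")
        fcfg = SiteFilterConfig(**config.filters)
        total_depth = None
        if "truth" in state:
            # Depth per site from the simulated counts.
            counts_file = state["counts_path"]
            if counts_file is not None and Path(counts_file).exists():
                _, _, counts = read_counts_tsv(counts_file)
                total_depth = counts.sum(axis=(1, 2))
                state["counts"] = counts
        table = call_snps(gl, fcfg, total_depth=total_depth)
        _write(table, out / "site_table.tsv")
        summary = pd.DataFrame(
            {
                "flag": ["snp_fail", "maf_fail", "depth_fail", "paralog_fail",
                         "pass"],
                "n_sites": [int(table[c].sum()) for c in
                            ("snp_fail", "maf_fail", "depth_fail",
                             "paralog_fail", "pass")],
            }
        )
        _write(summary, out / "filter_summary.tsv")
        state["site_table"] = table
        state["gl_filtered"] = apply_filters(gl, table)

    if "structure" in stages:
        glf = _require(state, "gl_filtered", "filter", "structure")
        pca = structure.covariance_pca(glf)
        np.savetxt(out / "covariance.tsv", pca.cov, delimiter="\t", fmt=_FLOAT_FMT)
        _write(pca.coordinates(k=10), out / "pca_coordinates.tsv")
        sub_idx = structure.balanced_subsample(
            glf.individuals, config.structure.get("subsample_to", 16),
            seed=stage_seed(config.seed, "pca"),
        )
        pca_sub = structure.covariance_pca(glf.subset_individuals(sub_idx))
        _write(pca_sub.coordinates(k=10), out / "pca_coordinates_subsampled.tsv")

        gl_adm = glf
        max_sites = config.structure.get("admix_max_sites")
        if max_sites and glf.n_sites > max_sites:
            stride = glf.n_sites // max_sites + 1
            gl_adm = glf.subset_sites(
                np.isin(np.arange(glf.n_sites),
                        np.arange(0, glf.n_sites, stride))
            )
        k_lo, k_hi = config.structure.get("k_range", [1, 8])
        fits = {}
        for K in range(k_lo, k_hi + 1):
            fits[K] = structure.admixture_em(
                gl_adm, K, seed=stage_seed(config.seed, f"admix{K}"),
                n_restarts=config.structure.get("n_restarts", 10),
                max_iter=config.structure.get("max_iter", 2000),
            )
            qdf = glf.individuals.copy()
            for k in range(K):
                qdf[f"Q{k + 1}"] = fits[K].Q[:, k]
            _write(qdf, out / f"admixture_Q_K{K}.tsv")
        aicc = structure.aicc_select(fits, gl_adm.n_individuals, gl_adm.n_sites)
        _write(aicc, out / "admixture_aicc.tsv")
        state["pca"] = pca
        state["admixture"] = fits

    if "diversity" in stages:
        glf = _require(state, "gl_filtered", "filter", "diversity")
        pops = glf.pop_indices()
        sfs_rows = []
        window_frames = []
        for name, idx in pops.items():
            saf = diversity.fold_saf(diversity.saf_likelihoods(glf.gls[:, idx]))
            sfs = diversity.sfs_em(saf)
            sfs_rows.append({"pop": name,
                             "sfs": " ".join(_FLOAT_FMT % v for v in sfs)})
            win = diversity.window_thetas(
                saf, sfs, glf.sites, state.get("chrom_lengths"),
                window_size=config.diversity.get("window_size", 5000),
                step=config.diversity.get("step", 1000),
            )
            win.insert(0, "pop", name)
            window_frames.append(win)
        pd.DataFrame(sfs_rows).to_csv(out / "sfs_folded.tsv", sep="\t",
                                      index=False, lineterminator="\n")
        windows = pd.concat(window_frames, ignore_index=True)
        _write(windows, out / "window_thetas.tsv")
        freqs, _ = estimate_maf_em(glf.gls)
        poly = np.isfinite(freqs) & (freqs > 1e-6) & (freqs < 1 - 1e-6)
        inb = diversity.inbreeding_em(glf.gls[poly], freqs[poly])
        inb.insert(0, "id", glf.individuals["id"].to_numpy())
        inb.insert(1, "pop", glf.individuals["pop"].to_numpy())
        _write(inb, out / "inbreeding.tsv")
        state["windows"] = windows

    if "differentiation" in stages:
        glf = _require(state, "gl_filtered", "filter", "differentiation")
        matrix, track = differentiation.pairwise_fst(glf)
        _write(matrix, out / "fst_pairwise.tsv")
        _write(track, out / "fst_sites.tsv")
        state["fst_matrix"] = matrix
        state["fst_track"] = track

    if "scan" in stages:
        glf = _require(state, "gl_filtered", "filter", "scan")
        table = state["site_table"]
        scfg = config.scan
        kept = table.loc[table["pass"]].reset_index(drop=True)
        scan_mask = (
            (kept["maf"] >= scfg.get("maf_min", 0.05))
            & (kept["snp_p"] <= scfg.get("snp_p_max", 1e-10))
        ).to_numpy()
        gls_scan = glf.subset_sites(scan_mask)
        counts = state.get("counts")
        if counts is not None:
            pass_idx = np.flatnonzero(table["pass"].to_numpy())[scan_mask]
            c_scan = counts[pass_idx]
            maj = gls_scan.sites["major"].map(BASE_INDEX).to_numpy()
            mino = gls_scan.sites["minor"].map(BASE_INDEX).to_numpy()
            pop_counts = scan.pop_allele_counts(
                c_scan, maj, mino, gls_scan.pop_indices()
            )
        else:
            raise PipelineError(
                "stage 'scan' requires read counts (run 'simulate' or supply "
                "a counts input)"
            )
        names = list(pop_counts)
        all_regions = []
        all_snps = []
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                tables = np.stack(
                    [np.stack([pop_counts[a][:, 0], pop_counts[a][:, 1]], axis=1),
                     np.stack([pop_counts[b][:, 0], pop_counts[b][:, 1]], axis=1)],
                    axis=1,
                )
                pvals = scan.fet_table(tables)
                res = scan.local_score_scan(
                    gls_scan.sites["chrom"].to_numpy(),
                    gls_scan.sites["pos"].to_numpy(),
                    pvals,
                    xi=scfg.get("xi", 2.0),
                    alpha=scfg.get("alpha", 0.01),
                    n_perm=scfg.get("n_perm", 1000),
                    seed=stage_seed(config.seed, f"scan_{a}_{b}"),
                )
                res.snps.insert(0, "pair", f"{a}-{b}")
                res.regions.insert(0, "pair", f"{a}-{b}")
                all_snps.append(res.snps)
                all_regions.append(res.regions)
        snps = pd.concat(all_snps, ignore_index=True)
        nonempty = [r for r in all_regions if len(r)]
        regions = (
            pd.concat(nonempty, ignore_index=True)
            if nonempty
            else pd.DataFrame(
                columns=["pair", "chrom", "start", "end", "peak", "n_snps"]
            )
        )
        _write(snps, out / "scan_snps.tsv")
        _write(regions, out / "scan_regions.tsv")
        state["scan_regions"] = regions
        state["scan_gl"] = gls_scan

    if "localpca" in stages:
        glf = _require(state, "gl_filtered", "filter", "localpca")
        try:
            lp = localpca.local_pca_scan(glf, window_snps=100)
            _write(lp, out / "localpca_windows.tsv")
            _write(lp.loc[lp["outlier"]], out / "localpca_outliers.tsv")
        except ValueError as err:
            (out / "localpca_windows.tsv").write_text(f"# skipped: {err}\n")

    if "linkage_dosage" in stages:
        regions = _require(state, "scan_regions", "scan", "linkage_dosage")
        glf = state["gl_filtered"]
        if len(regions):
            top = regions.loc[regions["peak"].idxmax()]
            chrom, start, end = top["chrom"], int(top["start"]), int(top["end"])
        else:  # no significant region: fall back to the densest chromosome
            chrom = glf.sites["chrom"].mode().iat[0]
            pos = glf.sites.loc[glf.sites["chrom"] == chrom, "pos"]
            start, end = int(pos.min()), int(pos.max())
        ld = linkage_dosage.ld_matrix(
            glf, chrom=chrom, start=start, end=end,
            max_dist=config.linkage.get("max_dist", 100_000),
            subsample_every=config.linkage.get("subsample_every", 10),
        )
        _write(ld, out / "ld_pairs.tsv")
        in_region = (
            (glf.sites["chrom"] == chrom)
            & (glf.sites["pos"] >= start)
            & (glf.sites["pos"] <= end)
        ).to_numpy()
        ref_pop = glf.individuals["pop"].iloc[0]
        if "GOA" in set(glf.individuals["pop"]):
            ref_pop = "GOA"
        dm = linkage_dosage.dosage_matrix(glf, in_region, reference_pop=ref_pop)
        _write(dm, out / "dosage_matrix.tsv")

    if "mito" in stages:
        counts = state.get("mito_counts")
        if counts is None:
            raise PipelineError(
                "stage 'mito' requires mito counts (run 'simulate' or supply "
                "a mito_counts input)"
            )
        individuals = state["mito_individuals"]
        mcfg = config.mito
        seqs = [
            mito.consensus_sequence(
                counts[i], individual_id=individuals["id"].iat[i],
                min_depth=mcfg.get("min_depth", 4),
                min_maf=mcfg.get("min_maf", 0.75),
            )
            for i in range(counts.shape[0])
        ]
        mito.write_fasta(seqs, out / "mito_consensus.fasta")
        pops = dict(zip(individuals["id"], individuals["pop"]))
        hapset = mito.haplotype_summary(seqs, pops)
        _write(hapset.diversity, out / "mito_diversity.tsv")
        hapset.pop_counts.rename_axis("haplotype").reset_index().to_csv(
            out / "mito_haplotype_freqs.tsv", sep="\t", index=False,
            lineterminator="\n")
        if len(hapset.haplotypes) >= 2:
            net = mito.haplotype_network(hapset)
            _write(net, out / "mito_network.tsv")
        state["hapset"] = hapset

    if "report" in stages:
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "stages": stages,
            "parameters": {
                "filters": config.filters,
                "structure": config.structure,
                "diversity": config.diversity,
                "scan": config.scan,
                "linkage": config.linkage,
                "mito": config.mito,
                "simdata": config.simdata,
            },
            "artifacts": {},
        }
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                digest = hashlib.sha256(p.read_bytes()).hexdigest()
                manifest["artifacts"][str(p.relative_to(out))] = digest
        with open(out / "manifest.json", "w", newline="\n") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
    return out
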