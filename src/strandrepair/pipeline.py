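"""End-to-end orchestration: simulate -> process -> metrics -> tables.

``run_pipeline`` executes a full demo-scale experiment: it generates one
shared genome/annotation, simulates an independent CPD-seq experiment (0 hr
plus a repair timepoint) for each requested genotype, quantifies bulk repair,
builds scaled bin profiles, asymmetry tables, TSS profiles, difference gene
matrices and SRAT contrasts for each test-vs-reference genotype pair, runs a
synthetic UV-survival assay, and writes everything as TSV/CSV/CDT plus a
JSON manifest.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as srio
from . import metrics, synthetic
from .core import GeneModel
from .gel import repair_ttest

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (YAML-loadable)."""

    outdir: str = "strandrepair_out"
    seed: int = 0
    timepoint: float = 2.0
    genotypes: tuple[str, ...] = ("WT", "set2", "rad16", "rad16set2")
    #: (test, reference) genotype pairs for difference matrices / contrasts
    contrasts: tuple[tuple[str, str], ...] = (("set2", "WT"),
                                              ("rad16set2", "rad16"))
    scaling: str = "gel"  # gel | intergenic_median | none
    smooth: int = 11
    flank_bin_bp: int = 167
    n_body_bins: int = 6
    tss_window: tuple[int, int] = (-200, 1000)
    gel_noise_sd: float = 0.02
    denylist: tuple[str, ...] = ()
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scaling not in ("gel", "intergenic_median", "none"):
            raise ValueError("scaling must be gel | intergenic_median | none")
        for test, ref in self.contrasts:
            for g in (test, ref):
                if g not in self.genotypes:
                    raise ValueError(f"contrast genotype {g!r} not in genotypes")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("genotypes", "denylist"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        if "tss_window" in raw:
            raw["tss_window"] = tuple(raw["tss_window"])
        return cls(**raw)


def _derived_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt * 7919 + 17) % (2 ** 31))


def survival_stats(assay: pd.DataFrame, reference_strain: str,
                   holm: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per strain x dose percent survival with SEM, plus two-sided Welch
    t-tests of each strain against the reference strain at each dose.

    ``assay`` columns: strain, dose, replicate, uv_count, control_count.
    Replicates with a zero control count are excluded (logged).  No
    multiple-testing correction by default; ``holm`` applies Holm's
    step-down across strains within each dose.
    """
    df = assay.copy()
    bad = df["control_count"] <= 0
    if bad.any():
        logger.info("survival: excluding %d replicates with zero control "
                    "count", int(bad.sum()))
        df = df[~bad]
    df["survival_pct"] = 100.0 * df["uv_count"] / df["control_count"]
    g = df.groupby(["strain", "dose"])["survival_pct"]
    summary = pd.DataFrame({
        "mean_survival_pct": g.mean(),
        "sem_survival_pct": g.std(ddof=1) / np.sqrt(g.count()),
        "n": g.count(),
    }).reset_index()

    tests = []
    for dose, sub in df.groupby("dose"):
        ref = sub.loc[sub["strain"] == reference_strain, "survival_pct"]
        if len(ref) < 2:
            continue
        for strain, vals in sub.groupby("strain")["survival_pct"]:
            if strain == reference_strain or len(vals) < 2:
                continue
            res = repair_ttest(vals.to_numpy(), ref.to_numpy())
            tests.append({"dose": dose, "strain": strain,
                          "reference": reference_strain,
                          "t": res["t"], "df": res["df"], "p": res["p"]})
    tests_df = pd.DataFrame(tests)
    if holm and len(tests_df):
        adj = []
        for dose, sub in tests_df.groupby("dose"):
            p = sub["p"].to_numpy()
            order = np.argsort(p)
            m = len(p)
            padj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * p[idx])
                padj[idx] = min(1.0, running)
            s = sub.copy()
            s["p_holm"] = padj
            adj.append(s)
        tests_df = pd.concat(adj, ignore_index=True)
    return summary, tests_df


def _simulate_survival_assay(genotypes: Sequence[str], seed: int,
                             n_replicates: int = 3,
                             cells_plated: int = 300) -> pd.DataFrame:
    """Colony-count survival assay consistent with the repair phenotypes:
    GG-NER loss (rad16) is UV-sensitive and additionally deleting SET2
    partially restores survival via cryptic TC-NER of the NTS."""
    base = {"WT": 0.80, "set2": 0.55, "rad16": 0.10, "rad16set2": 0.30,
            "rad26": 0.60}
    rng = np.random.default_rng(seed)
    rows = []
    for dose, dose_factor in ((50, 1.0), (100, 0.45)):
        for g in genotypes:
            p = base.get(g, 0.5) * dose_factor
            for rep in range(n_replicates):
                control = int(rng.poisson(cells_plated))
                uv = int(rng.binomial(control, min(p, 1.0)))
                rows.append({"strain": g, "dose": dose, "replicate": rep,
                             "uv_count": uv, "control_count": control})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the simulate->process->metrics demo pipeline; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = float(config.timepoint)

    sim_cfg = synthetic.SimulationConfig(seed=config.seed, **config.simulation)
    base_gt = synthetic.generate_genome_and_genes(sim_cfg)
    logger.info("simulated %d genes on %d chrom(s)",
                len(base_gt.genes), sim_cfg.n_chroms)

    manifest: dict = {
        "version": __version__, "seed": config.seed,
        "timepoint": t, "scaling": config.scaling,
        "n_genes": len(base_gt.genes),
        "genotypes": list(config.genotypes),
        "outputs": [], "scale_factors": {}, "gene_counts": {},
    }
    outputs: list[str] = manifest["outputs"]

    def _write(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        outputs.append(name)
        return path

    _write("genome.fa", lambda p: srio.write_fasta(p, base_gt.genome))
    _write("genes.bed", lambda p: srio.write_genes(
        p, base_gt.genes, covariates_path=outdir / "gene_covariates.tsv"))
    outputs.append("gene_covariates.tsv")
    _write("dyads.bedgraph", lambda p: srio.write_bedgraph(
        p, base_gt.dyad_coverage()))

    profiles: dict[str, metrics.BinProfile] = {}
    tracks: dict[str, dict[float, object]] = {}
    per_genotype_scale: dict[str, float] = {}

    for i, genotype in enumerate(config.genotypes):
        gt = synthetic.GroundTruth(config=sim_cfg, genome=base_gt.genome,
                                   genes=base_gt.genes, dyads=base_gt.dyads)
        gseed = _derived_seed(config.seed, i + 1)
        observed = synthetic.simulate_timecourse(gt, genotype, [t], seed=gseed)
        tracks[genotype] = observed
        for tp, track in observed.items():
            prefix = outdir / f"lesions_{genotype}_{tp:g}hr"
            srio.write_track(prefix, track)
            outputs.append(f"lesions_{genotype}_{tp:g}hr.plus.bedgraph")
            outputs.append(f"lesions_{genotype}_{tp:g}hr.minus.bedgraph")

        curve = synthetic.simulate_gel_curve(
            gt, [t], noise_sd=config.gel_noise_sd, n_replicates=3,
            seed=_derived_seed(config.seed, 100 + i))
        _write(f"gel_{genotype}.csv",
               lambda p, c=curve: c.summary().to_csv(p, index=False))

        profile = metrics.bin_profile(observed[t], observed[0.0],
                                      base_gt.genes,
                                      flank_bin_bp=config.flank_bin_bp,
                                      n_body_bins=config.n_body_bins,
                                      denylist=config.denylist)
        scale = 1.0
        if config.scaling == "gel":
            profile, scale = metrics.gel_scale(
                profile, observed[t], observed[0.0],
                curve.fraction_remaining(t))
        per_genotype_scale[genotype] = scale
        manifest["scale_factors"][genotype] = scale
        manifest["gene_counts"][genotype] = profile.n_genes
        profiles[genotype] = profile

        tssp = metrics.tss_profile(observed[t], observed[0.0], base_gt.genes,
                                   base_gt.chrom_lengths,
                                   window=config.tss_window,
                                   smooth=config.smooth,
                                   dyads=base_gt.dyads, scale_factor=scale)
        _write(f"tss_{genotype}.tsv",
               lambda p, x=tssp: x.to_frame().to_csv(p, sep="\t", index=False))

    for test, ref in config.contrasts:
        pt, pr = profiles[test], profiles[ref]
        if config.scaling == "intergenic_median":
            pt, m = metrics.intergenic_median_scale(pt, pr)
            manifest["scale_factors"][f"{test}_vs_{ref}_median"] = m
            profiles[test] = pt

    for genotype in config.genotypes:
        profile = profiles[genotype]
        _write(f"bins_{genotype}.tsv",
               lambda p, x=profile: x.to_frame().to_csv(p, sep="\t", index=False))
        _write(f"asymmetry_{genotype}.tsv",
               lambda p, x=profile: metrics.asymmetry_frame(x)
               .to_csv(p, sep="\t", index=False))

    srat_by_id = {g.gene_id: g.is_srat for g in base_gt.genes}
    for test, ref in config.contrasts:
        order_key = "srat_first" if test.startswith("rad16") else "expr_log2fc"
        mat = metrics.gene_matrix(
            tracks[test][t], tracks[test][0.0], base_gt.genes,
            order_key=order_key,
            reference_pair=(tracks[ref][t], tracks[ref][0.0]),
            flank_bin_bp=config.flank_bin_bp,
            n_body_bins=config.n_body_bins,
            scale_factor=profiles[test].scale_factor,
            ref_scale_factor=profiles[ref].scale_factor,
            denylist=config.denylist)
        stem = f"matrix_{test}_vs_{ref}"
        _write(f"{stem}.tsv",
               lambda p, x=mat: x.data.to_csv(p, sep="\t"))
        _write(f"{stem}.cdt", lambda p, x=mat: x.to_cdt(p))
        contrast = metrics.srat_contrast(mat, srat_by_id,
                                         seed=_derived_seed(config.seed, 999))
        _write(f"srat_contrast_{test}_vs_{ref}.tsv",
               lambda p, x=contrast: x.to_csv(p, sep="\t", index=False))

    assay = _simulate_survival_assay(config.genotypes,
                                     seed=_derived_seed(config.seed, 2024))
    _write("survival_counts.csv", lambda p: assay.to_csv(p, index=False))
    reference = "WT" if "WT" in config.genotypes else config.genotypes[0]
    summary, tests = survival_stats(assay, reference_strain=reference)
    _write("survival_summary.tsv",
           lambda p: summary.to_csv(p, sep="\t", index=False))
    _write("survival_tests.tsv",
           lambda p: tests.to_csv(p, sep="\t", index=False))

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("wrote %d outputs to %s", len(outputs), outdir)
    return manifest
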