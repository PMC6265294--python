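"""End-to-end reproducible runs: simulate -> quantify -> metrics -> downstream.

A run is driven by a :class:`RunConfig` (YAML-serializable; unknown keys are
rejected so typos cannot silently change an analysis).  Every published
analysis threshold is a named config field with the study's value as default:
0.95 dominance cutoff, |dMAF| >= 0.15 with p <= 0.05, FDR 0.05 and 1 % read
fraction for the co-occurrence artifact filter, 3/7/30/100-read detection and
coverage cutoffs, 2,500-iteration burn-in.  ``run_pipeline`` writes every
stage's outputs plus a manifest with content checksums; rerunning with the
same config and seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dilution, metrics, quantify, stability, synth, variants

logger = logging.getLogger("clonetrace")

__all__ = ["RunConfig", "SimulateConfig", "Thresholds", "run_pipeline",
           "make_fixtures", "ConfigError"]


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration content."""


@dataclass(frozen=True)
class SimulateConfig:
    n_cells: int = 30_000
    moi: float = 0.2
    p_tic: float = 0.04
    n_mice: int = 2
    n_lung: int = 2
    n_liver: int = 1
    n_brain: int = 0
    n_seeders: int = 100
    n_dominant: int = 5
    dominance_factor: float = 500.0
    reads_per_sample: int = 20000
    error_rate: float = 0.001
    junk_fraction: float = 0.05
    library_size: int = 100
    library_min_dist: int = 3
    nb_mean: float = 100.0
    nb_dispersion: float = 1.0
    seeding_alpha: float = 1.0


@dataclass(frozen=True)
class Thresholds:
    dominance_threshold: float = 0.95
    delta_maf: float = 0.15
    p_value: float = 0.05
    fdr: float = 0.05
    cooccurrence_fraction: float = 0.01
    min_alt_targeted: int = 3
    de_novo_alt_cutoff: int = 7
    min_coverage_wes: int = 30
    min_coverage_barcoded: int = 100
    burn_in: int = 2500


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    outdir: str = "clonetrace_run"
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(dc_type, payload, path):
            names = {f.name: f for f in dataclasses.fields(dc_type)}
            unknown = set(payload) - set(names)
            if unknown:
                raise ConfigError(
                    f"unknown config key(s) {sorted(unknown)} at {path!r}")
            kwargs = {}
            for key, value in payload.items():
                f = names[key]
                if dataclasses.is_dataclass(f.type) or f.type in (
                        SimulateConfig, Thresholds):
                    kwargs[key] = build(f.type, value, f"{path}.{key}")
                else:
                    kwargs[key] = value
            return dc_type(**kwargs)

        # field types may be strings under `from __future__ import annotations`
        sub = {"simulate": SimulateConfig, "thresholds": Thresholds}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ConfigError(f"unknown config key(s) {sorted(unknown)}")
        kwargs = {}
        for key, value in data.items():
            if key in sub:
                kwargs[key] = build(sub[key], value or {}, key)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sim_params(cfg: SimulateConfig) -> synth.SimParams:
    mice = []
    for i in range(cfg.n_mice):
        name = chr(ord("A") + i)
        lesions = [synth.LesionSpec("MFP", "MFP")]
        for site, count in (("lung", cfg.n_lung), ("liver", cfg.n_liver),
                            ("brain", cfg.n_brain)):
            lesions += [synth.LesionSpec(site, f"{site}{j + 1}",
                                         cfg.n_seeders)
                        for j in range(count)]
        mice.append(synth.MouseSpec(name, tuple(lesions)))
    return synth.SimParams(
        n_cells=cfg.n_cells, moi=cfg.moi, p_tic=cfg.p_tic, mice=tuple(mice),
        n_dominant=cfg.n_dominant, dominance_factor=cfg.dominance_factor,
        reads_per_sample=cfg.reads_per_sample, error_rate=cfg.error_rate,
        junk_fraction=cfg.junk_fraction, nb_mean=cfg.nb_mean,
        nb_dispersion=cfg.nb_dispersion, seeding_alpha=cfg.seeding_alpha)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest.

    Stages: simulate barcoded mice and write FASTQ/FASTA/sample sheet;
    quantify barcode pairs; compute the clonal report; fit the published
    limiting-dilution tables; classify dMAF on a synthetic subclone phantom;
    run the cluster-stability test on a simulated trace.  A stage failure
    aborts the run (the manifest is still written, marked incomplete, with
    the failing stage named).
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "seed": config.seed,
                      "outputs": {}, "stages": {}, "complete": False}
    manifest_path = outdir / "manifest.json"

    def record(stage: str, *paths: Path):
        manifest["stages"][stage] = "ok"
        for p in paths:
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)

    stage = "simulate"
    try:
        cfg = config.simulate
        th = config.thresholds
        library = synth.make_half_library(
            cfg.library_size, min_dist=cfg.library_min_dist,
            seed=config.seed)
        params = _sim_params(cfg)
        gt, reads = synth.simulate_experiment(params, library,
                                              seed=config.seed)
        fastq_dir = outdir / "fastq"
        fastq_dir.mkdir(exist_ok=True)
        written = []
        for sample, seqs in reads.items():
            path = fastq_dir / f"{sample}.fastq"
            synth.write_fastq(seqs, path)
            written.append(path)
        lib_path = outdir / "library.fasta"
        synth.write_fasta(library, lib_path)
        sheet_path = outdir / "sample_sheet.csv"
        gt.sample_sheet.to_csv(sheet_path, index=False)
        synth.write_ground_truth(gt, outdir / "ground_truth")
        record(stage, lib_path, sheet_path, *written)

        stage = "quantify"
        matrix = quantify.count_pairs(
            {s: [quantify.ReadRecord(f"r{i}", seq)
                 for i, seq in enumerate(seqs)]
             for s, seqs in reads.items()}, library)
        counts_path = outdir / "counts.tsv"
        cpm_path = outdir / "cpm.tsv"
        matrix.to_tsv(counts_path, cpm_path)
        log_path = outdir / "filter_log.json"
        with open(log_path, "w") as fh:
            json.dump({s: lg.as_dict() for s, lg in matrix.logs.items()},
                      fh, indent=2)
        record(stage, counts_path, cpm_path, log_path)

        stage = "metrics"
        metas = metrics.load_sample_sheet(sheet_path)
        report = metrics.clonal_report(matrix, metas,
                                       threshold=th.dominance_threshold)
        report.to_files(outdir / "metrics")
        record(stage, outdir / "metrics" / "per_sample.tsv",
               outdir / "metrics" / "per_metastasis.tsv")

        stage = "mif"
        mif = {}
        for (model, organ), rows in dilution.TABLE1.items():
            est = dilution.fit_single_hit(
                dilution.DilutionAssay(tuple(rows)))
            mif[f"{model}_{organ}"] = {
                "percent": est.percent_1dp,
                "ci_percent": list(est.ci_percent)}
        mif_path = outdir / "mif.json"
        with open(mif_path, "w") as fh:
            json.dump(mif, fh, indent=2)
        record(stage, mif_path)

        stage = "mafdyn"
        phantom = default_phantom()
        maf_table = synth.simulate_maf_table(phantom, seed=config.seed)
        maf_path = outdir / "variant_table.tsv"
        maf_table.to_csv(maf_path, sep="\t", index=False)
        primaries = [s for s in phantom.sample_ids if s.startswith("MFP")]
        mets = [s for s in phantom.sample_ids if s.startswith("lung")]
        dmaf = variants.delta_maf(maf_table, mets, primaries,
                                  min_delta=th.delta_maf, alpha=th.p_value)
        dmaf_path = outdir / "delta_maf.tsv"
        dmaf.to_csv(dmaf_path, sep="\t", index=False)
        record(stage, maf_path, dmaf_path)

        stage = "stability"
        true_clusters = {f"v{i:03d}": i % 4 for i in range(40)}
        trace = synth.simulate_assignment_trace(true_clusters, n_iters=2000,
                                                flip_rate=0.05,
                                                seed=config.seed)
        rep = stability.test_cluster_robustness(
            trace, burn_in=min(th.burn_in, trace.n_iterations // 2))
        stab_path = outdir / "stability.tsv"
        rep.table.to_csv(stab_path, sep="\t", index=False)
        record(stage, stab_path)
    except Exception:
        manifest["stages"][stage] = "failed"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
        logger.exception("stage %s failed; partial outputs retained", stage)
        raise
    manifest["complete"] = True
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def default_phantom(n_private: int = 10, n_clonal: int = 10,
                    depth: int = 1500, n_primaries: int = 3,
                    n_mets: int = 6, mixing_primary: float = 0.10,
                    mixing_met: float = 0.70) -> synth.SubclonePhantom:
    """Two-subclone phantom: one metastasis-enriched subclone, one background.

    Clonal mutations are carried by both subclones; private mutations only by
    the enriched one, whose mixing proportion rises from 10 % in primaries to
    70 % in metastases.
    """
    n_var = n_private + n_clonal
    genotype = np.zeros((n_var, 2), dtype=int)
    genotype[:n_private, 1] = 1          # private to the enriched subclone
    genotype[n_private:, :] = 1          # clonal
    n_samples = n_primaries + n_mets
    mixing = np.zeros((2, n_samples))
    mixing[1, :n_primaries] = mixing_primary
    mixing[1, n_primaries:] = mixing_met
    mixing[0] = 1 - mixing[1]
    sample_ids = tuple([f"MFP{i + 1}" for i in range(n_primaries)]
                       + [f"lung{i + 1}" for i in range(n_mets)])
    variant_ids = tuple([f"priv{i:03d}" for i in range(n_private)]
                        + [f"clon{i:03d}" for i in range(n_clonal)])
    return synth.SubclonePhantom(
        genotype=genotype, mixing=mixing,
        depth=np.full((n_var, n_samples), depth),
        variant_ids=variant_ids, sample_ids=sample_ids)


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> dict:
    """Write a small dataset exercising every stage.

    Contents: a 100-sequence half-barcode FASTA; FASTQs for 2 mice x (1 MFP
    + 2 lung + 1 liver) at 50k reads each with ground truth; the published
    limiting-dilution counts as CSV; a subclone-phantom variant table; a
    500-iteration assignment trace.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = synth.make_half_library(100, seed=seed)
    synth.write_fasta(library, outdir / "library.fasta")
    mice = tuple(
        synth.MouseSpec(name, (
            synth.LesionSpec("MFP", "MFP"),
            synth.LesionSpec("lung", "lung1", 60),
            synth.LesionSpec("lung", "lung2", 60),
            synth.LesionSpec("liver", "liver1", 60),
        )) for name in ("A", "B"))
    params = synth.SimParams(mice=mice, reads_per_sample=50_000)
    gt, reads = synth.simulate_experiment(params, library, seed=seed)
    fastq_dir = outdir / "fastq"
    fastq_dir.mkdir(exist_ok=True)
    for sample, seqs in reads.items():
        synth.write_fastq(seqs, fastq_dir / f"{sample}.fastq")
    gt.sample_sheet.to_csv(outdir / "sample_sheet.csv", index=False)
    synth.write_ground_truth(gt, outdir / "ground_truth")
    for (model, organ), rows in dilution.TABLE1.items():
        pd.DataFrame(rows, columns=["dose", "tested", "positive"]).to_csv(
            outdir / f"dilution_{model}_{organ}.csv", index=False)
    synth.simulate_maf_table(default_phantom(), seed=seed).to_csv(
        outdir / "variant_table.tsv", sep="\t", index=False)
    true_clusters = {f"v{i:03d}": i % 4 for i in range(40)}
    trace = synth.simulate_assignment_trace(true_clusters, n_iters=500,
                                            flip_rate=0.05, seed=seed)
    stability.write_trace_tsv(trace, outdir / "trace.tsv")
    return {"outdir": str(outdir),
            "samples": list(reads),
            "library_size": len(library)}
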