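"""End-to-end orchestration: simulate -> nucleosomes -> profiles -> DMRs ->
FFT -> clusters, with a reproducible manifest.

Each stage reads its inputs from the output directory (or from explicitly
supplied files), writes plain-text outputs there, and registers them in a
manifest with SHA-256 checksums, so identical configurations and seeds give
byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dmr, io, nucleosomes, periodicity, profiles, simulate, som
from .errors import DependencyError, InvalidConfigError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "nucleosomes", "profile", "dmr", "fft", "cluster")


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    genotypes: tuple[str, ...] = simulate.GENOTYPES
    simulation: simulate.SimulationConfig | None = None
    params: dict[str, dict] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise InvalidConfigError(f"unknown stages: {sorted(unknown)}")
        if self.simulation is None:
            self.simulation = simulate.SimulationConfig(seed=self.seed)

    @classmethod
    def from_file(cls, path: str | Path, out_dir: str | Path,
                  seed: int | None = None) -> "RunConfig":
        values = io.read_config(path)
        sim_kwargs = {k[4:]: v for k, v in values.items()
                      if k.startswith("sim.")}
        run_seed = int(seed if seed is not None else values.get("seed", 0))
        sim = simulate.SimulationConfig(seed=run_seed, **sim_kwargs)
        stages = tuple(values.get("stages", list(STAGES)))
        genotypes = tuple(values.get("genotypes", list(simulate.GENOTYPES)))
        return cls(out_dir=Path(out_dir), seed=run_seed, stages=stages,
                   genotypes=genotypes, simulation=sim)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _require(config: RunConfig, stage: str, *names: str) -> dict[str, Path]:
    paths = {}
    for name in names:
        candidate = Path(config.inputs.get(name,
                                           config.out_dir / name))
        if not candidate.exists():
            raise DependencyError(
                f"stage {stage!r} requires {name!r}; run the producing stage "
                "first or supply it via inputs"
            )
        paths[name] = candidate
    return paths


def _stage_simulate(config: RunConfig) -> dict[str, Path]:
    sim = config.simulation
    layout = simulate.generate_layout(sim)
    nmap = simulate.simulate_true_nucleosomes(layout, sim)
    replicates = simulate.simulate_fragments(nmap, sim, n_replicates=2)
    out = config.out_dir
    outputs: dict[str, Path] = {}

    feats = layout.features.assign(name=layout.features["feature_class"])
    io.write_bed(feats, out / "features.bed", columns=["name"])
    outputs["features.bed"] = out / "features.bed"
    parts = layout.gene_parts.assign(name=layout.gene_parts["kind"])
    io.write_bed(parts, out / "gene_parts.bed", columns=["name"])
    outputs["gene_parts.bed"] = out / "gene_parts.bed"
    dyads = nmap.dyads.assign(start=nmap.dyads["dyad"],
                              end=nmap.dyads["dyad"] + 1,
                              name=nmap.dyads["feature_class"])
    io.write_bed(dyads, out / "true_dyads.bed", columns=["name"])
    outputs["true_dyads.bed"] = out / "true_dyads.bed"
    for rep, frame in enumerate(replicates, start=1):
        path = out / f"fragments_rep{rep}.bed"
        io.write_bed(frame, path)
        outputs[path.name] = path
    for genotype in config.genotypes:
        records = simulate.simulate_methylome(layout, nmap, genotype, sim)
        path = out / f"cx_{genotype}.tsv"
        io.write_cx_report(records, path)
        outputs[path.name] = path
    return outputs


def _stage_nucleosomes(config: RunConfig) -> dict[str, Path]:
    paths = _require(config, "nucleosomes", "fragments_rep1.bed",
                     "fragments_rep2.bed")
    params = config.params.get("nucleosomes", {})
    reps = []
    for name in ("fragments_rep1.bed", "fragments_rep2.bed"):
        frags = nucleosomes.filter_fragments(io.read_bed(paths[name]))
        peaks = nucleosomes.call_peaks(
            frags, bandwidth=params.get("bandwidth", 15.0))
        reps.append(nucleosomes.filter_peak_width(
            peaks, max_width=params.get("max_width", 140)))
    calls = nucleosomes.classify_positioning(reps[0], reps[1])
    out = config.out_dir
    bed = calls.assign(name="group" + calls["group"].astype(str),
                       score=(calls["best_overlap"] * 1000).round().astype(int))
    io.write_bed(bed, out / "nucleosome_calls.bed", columns=["name", "score"])
    dyad_bed = calls.assign(start=calls["dyad"], end=calls["dyad"] + 1,
                            name="group" + calls["group"].astype(str))
    io.write_bed(dyad_bed, out / "dyads.bed", columns=["name"])
    return {"nucleosome_calls.bed": out / "nucleosome_calls.bed",
            "dyads.bed": out / "dyads.bed"}


def _read_calls(path: Path) -> pd.DataFrame:
    bed = io.read_bed(path)
    group = bed["name"].str.removeprefix("group").astype(int)
    dyad = (bed["start"] + bed["end"]) // 2
    return bed.assign(group=group, dyad=dyad)


def _stage_profile(config: RunConfig) -> dict[str, Path]:
    needed = ["nucleosome_calls.bed"] + [f"cx_{g}.tsv"
                                         for g in config.genotypes]
    paths = _require(config, "profile", *needed)
    params = config.params.get("profile", {})
    flank = params.get("flank", 200)
    bin_size = params.get("bin", 1)
    context = params.get("context", "CG")
    calls = _read_calls(paths["nucleosome_calls.bed"])
    anchors = calls[calls["group"] == 1][["chrom", "dyad"]].rename(
        columns={"dyad": "pos"})
    outputs = {}
    for genotype in config.genotypes:
        records = io.read_cx_report(paths[f"cx_{genotype}.tsv"])
        prof = profiles.profile_around_anchors(
            records, anchors, flank=flank, bin_size=bin_size,
            context=context, label=genotype)
        path = config.out_dir / f"profile_{context}_{genotype}.tsv"
        io.write_profile_tsv(prof, path)
        outputs[path.name] = path
    return outputs


def _stage_dmr(config: RunConfig) -> dict[str, Path]:
    params = config.params.get("dmr", {})
    wt = params.get("wt", "WT")
    mut = params.get("mut", "ddm1")
    other = params.get("other", "h1")
    paths = _require(config, "dmr", "features.bed",
                     *[f"cx_{g}.tsv" for g in (wt, mut, other)])
    records = {g: io.read_cx_report(paths[f"cx_{g}.tsv"])
               for g in (wt, mut, other)}
    windows = dmr.window_counts(records, window=params.get("window", 50),
                                context=params.get("context", "CHH"))
    dmrs = dmr.call_dmrs(windows, wt, mut, other,
                         min_wt=params.get("min_wt", 0.10),
                         min_loss=params.get("min_loss", 0.30),
                         alpha=params.get("alpha", 0.01))
    features = io.read_bed(paths["features.bed"])
    tes = features[features["name"].isin(["het_TE", "eu_TE"])]
    dmrs = dmr.require_te_overlap(dmrs, tes)
    out = config.out_dir / "dmrs.bed"
    score = (-10 * np.log10(dmrs["min_p"].clip(lower=1e-300))).round()
    bed = dmrs.assign(name=dmrs["dependency"], score=score.astype(int))
    io.write_bed(bed, out, columns=["name", "score"])
    return {"dmrs.bed": out}


def _stage_fft(config: RunConfig) -> dict[str, Path]:
    params = config.params.get("fft", {})
    genotype = params.get("genotype", "WT")
    context = params.get("context", "CG")
    paths = _require(config, "fft", "fragments_rep1.bed", "features.bed",
                     f"cx_{genotype}.tsv")
    frags = io.read_bed(paths["fragments_rep1.bed"])
    features = io.read_bed(paths["features.bed"])
    mask = features[features["name"] == "het_TE"]
    anchors = periodicity.select_147bp(frags, mask=mask if len(mask) else None)
    records = io.read_cx_report(paths[f"cx_{genotype}.tsv"])
    vector = periodicity.per_base_vector(anchors, records, context=context)
    result = periodicity.periodogram(vector)
    out = config.out_dir
    vector.to_frame().to_csv(out / "per_base_vector.tsv", sep="\t",
                             index=False, float_format="%.6g")
    result.to_frame().to_csv(out / "periodogram.tsv", sep="\t", index=False,
                             float_format="%.6g")
    peak = periodicity.peak_period(result)
    logger.info("peak period %.2f bp over %d anchors", peak, vector.n_anchors)
    return {"per_base_vector.tsv": out / "per_base_vector.tsv",
            "periodogram.tsv": out / "periodogram.tsv"}


def _stage_cluster(config: RunConfig) -> dict[str, Path]:
    params = config.params.get("cluster", {})
    genotype = params.get("genotype", "h1ddm1")
    context = params.get("context", "CG")
    paths = _require(config, "cluster", "nucleosome_calls.bed",
                     f"cx_{genotype}.tsv")
    calls = _read_calls(paths["nucleosome_calls.bed"])
    anchors = calls[calls["group"] == 1][["chrom", "dyad"]].rename(
        columns={"dyad": "pos"})
    if anchors.empty:
        raise DependencyError("stage 'cluster' found no group-1 nucleosomes")
    records = io.read_cx_report(paths[f"cx_{genotype}.tsv"])
    matrix = som.build_locus_matrix(anchors, records,
                                    flank=params.get("flank", 250),
                                    bin_size=params.get("bin", 10),
                                    context=context)
    k = min(params.get("k", 5), len(anchors))
    assignment = som.som_cluster(matrix, k=k,
                                 epochs=params.get("epochs", 100),
                                 seed=config.seed)
    phased = som.identify_phased_cluster(assignment)
    out = config.out_dir / "clusters.bed"
    bed = matrix.anchors.assign(start=matrix.anchors["pos"],
                                end=matrix.anchors["pos"] + 1,
                                name=[f"C{l}" for l in assignment.labels])
    io.write_bed(bed, out, columns=["name"])
    logger.info("phased cluster: C%d (%d loci)", phased,
                int((assignment.labels == phased).sum()))
    return {"clusters.bed": out}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "nucleosomes": _stage_nucleosomes,
    "profile": _stage_profile,
    "dmr": _stage_dmr,
    "fft": _stage_fft,
    "cluster": _stage_cluster,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; return the manifest."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "completed": []}
    ordered = [s for s in STAGES if s in config.stages]
    for stage in ordered:
        logger.info("[%s] starting", stage)
        start = time.time()
        outputs = _STAGE_FUNCS[stage](config)
        manifest["stages"][stage] = {
            "params": config.params.get(stage, {}),
            "outputs": {name: {"sha256": _sha256(path),
                               "bytes": path.stat().st_size}
                        for name, path in sorted(outputs.items())},
        }
        manifest["completed"].append(stage)
        logger.info("[%s] done in %.1f s", stage, time.time() - start)
    path = config.out_dir / "manifest.json"
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    logger.info("wrote manifest with %d stages to %s",
                len(manifest["completed"]), path)
    return manifest
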