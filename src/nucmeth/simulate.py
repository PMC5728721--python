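"""Synthetic genomes, nucleosome maps, MNase fragments and bisulfite methylomes.

This module generates data with the statistical structure that the downstream
analyses assume, so that every stage of the toolkit can be exercised without
sequencing data.  The model is deliberately simple:

* a genome is a set of chromosomes tiled with annotated features
  (heterochromatic TEs, euchromatic TEs, genes with exon/intron structure);
* nucleosomes are placed as alternating 147 bp cores and stochastically
  sampled linkers, so true dyads are known exactly;
* MNase fragments are drawn per nucleosome with Normal positioning jitter
  around the true dyad and a discrete fragment-length distribution;
* per-cytosine bisulfite counts are Binomial draws at a rate determined by
  the position of the cytosine relative to the nearest dyad: a core rate with
  a cosine rotational modulation (helical-repeat period, default 10 bp, with
  the cosine maximum at the dyad) inside the core, a linker rate outside, at
  Poisson sequencing coverage.

Genotypes ("WT", "h1", "ddm1", "h1ddm1") differ only in their per-context
core/linker rates and rotational amplitudes.  Sequence itself is never
generated: cytosine positions, strands and contexts (CG/CHG/CHH) are sampled
as labels at fixed densities, identically for every genotype, so that
genotype comparisons see the same sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
GENOTYPES = ("WT", "h1", "ddm1", "h1ddm1")
FEATURE_CLASSES = ("het_TE", "eu_TE", "gene")

# rng stream ids; every stream is seeded as default_rng([seed, STREAM, ...])
_STREAM_LAYOUT = 101
_STREAM_NUCLEOSOMES = 102
_STREAM_FRAGMENTS = 103
_STREAM_CYTOSINE_SITES = 104
_STREAM_METHYLOME = 105
_STREAM_DMR_STUDY = 106
_STREAM_TE_SCORES = 108
_STREAM_LOCUS_MATRIX = 109


@dataclass(frozen=True)
class ContextRates:
    """Methylation rates for one genotype in one sequence context."""

    core_rate: float
    linker_rate: float
    rotational_amplitude: float = 0.0

    def validate(self) -> None:
        for name in ("core_rate", "linker_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        amp = self.rotational_amplitude
        if amp < 0:
            raise InvalidConfigError("rotational_amplitude must be >= 0")
        if amp > min(self.core_rate, 1.0 - self.core_rate) + 1e-12:
            raise InvalidConfigError(
                "rotational_amplitude must not exceed min(core_rate, 1-core_rate)"
            )


def default_genotype_params() -> dict[str, dict[str, ContextRates]]:
    """Per-genotype, per-context (core, linker, rotational amplitude) defaults.

    The qualitative structure: mild core depletion in WT/h1, strong core
    depletion in ddm1, strong core depletion with high linkers in h1ddm1,
    and rotational modulation present in every genotype except ddm1.
    """
    return {
        "WT": {
            "CG": ContextRates(0.85, 0.90, 0.05),
            "CHG": ContextRates(0.55, 0.70, 0.05),
            "CHH": ContextRates(0.12, 0.25, 0.04),
        },
        "h1": {
            "CG": ContextRates(0.88, 0.92, 0.04),
            "CHG": ContextRates(0.60, 0.78, 0.05),
            "CHH": ContextRates(0.14, 0.32, 0.04),
        },
        "ddm1": {
            "CG": ContextRates(0.25, 0.45, 0.00),
            "CHG": ContextRates(0.15, 0.35, 0.00),
            "CHH": ContextRates(0.05, 0.12, 0.00),
        },
        "h1ddm1": {
            "CG": ContextRates(0.25, 0.85, 0.02),
            "CHG": ContextRates(0.15, 0.60, 0.02),
            "CHH": ContextRates(0.06, 0.30, 0.02),
        },
    }


@dataclass
class SimulationConfig:
    """Free parameters of the generator.

    positioning_sd is per feature class (bp of Normal jitter of observed
    fragment midpoints around the true dyad); "intergenic" covers dyads not
    inside any annotated feature.  fragment_length_dist, when given, is a
    {length: probability} mapping; otherwise lengths are a rounded Normal.
    coverage_mean is both the mean fragment count per nucleosome (per
    replicate) and the mean read count per cytosine.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    feature_fractions: dict[str, float] = field(
        default_factory=lambda: {"het_TE": 0.40, "eu_TE": 0.10, "gene": 0.30}
    )
    nucleosome_length: int = 147
    linker_length_mean: float = 30.0
    linker_length_sd: float = 5.0
    positioning_sd: dict[str, float] = field(
        default_factory=lambda: {
            "het_TE": 2.0,
            "eu_TE": 15.0,
            "gene": 8.0,
            "intergenic": 25.0,
        }
    )
    fragment_length_dist: dict[int, float] | None = None
    fragment_length_mean: float = 147.0
    fragment_length_sd: float = 8.0
    coverage_mean: float = 10.0
    cytosine_density: float = 0.18
    context_probs: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.17, "CHG": 0.17, "CHH": 0.66}
    )
    genotype_params: dict[str, dict[str, ContextRates]] = field(
        default_factory=default_genotype_params
    )
    rotational_period: float = 10.0

    def __post_init__(self) -> None:
        if sum(self.feature_fractions.values()) > 1.0 + 1e-9:
            raise InvalidConfigError("feature fractions must sum to <= 1")
        if any(f < 0 for f in self.feature_fractions.values()):
            raise InvalidConfigError("feature fractions must be >= 0")
        if any(sd < 0 for sd in self.positioning_sd.values()):
            raise InvalidConfigError("positioning_sd must be >= 0")
        if self.coverage_mean < 0:
            raise InvalidConfigError("coverage_mean must be >= 0")
        if not 0.0 < self.cytosine_density <= 1.0:
            raise InvalidConfigError("cytosine_density must be in (0, 1]")
        if abs(sum(self.context_probs.values()) - 1.0) > 1e-9:
            raise InvalidConfigError("context_probs must sum to 1")
        if self.rotational_period <= 0:
            raise InvalidConfigError("rotational_period must be > 0")
        if self.fragment_length_dist is not None:
            probs = np.asarray(list(self.fragment_length_dist.values()), float)
            if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
                raise InvalidConfigError("fragment_length_dist must be a distribution")
        for genotype, per_context in self.genotype_params.items():
            for context, rates in per_context.items():
                if context not in CONTEXTS:
                    raise InvalidConfigError(
                        f"unknown context {context!r} for genotype {genotype!r}"
                    )
                rates.validate()

    def positioning_sd_for(self, feature_class: str) -> float:
        return self.positioning_sd.get(
            feature_class, self.positioning_sd.get("intergenic", 0.0)
        )


@dataclass
class GenomeLayout:
    """Annotated intervals of a synthetic genome (0-based half-open)."""

    chrom_sizes: dict[str, int]
    features: pd.DataFrame  # chrom, start, end, feature_class, strand, feature_id
    gene_parts: pd.DataFrame  # chrom, start, end, kind(exon|intron), gene_id


@dataclass
class TrueNucleosomeMap:
    """Ground-truth dyad positions with feature-class labels."""

    dyads: pd.DataFrame  # chrom, dyad, feature_class (sorted by chrom, dyad)
    nucleosome_length: int = 147

    def for_chrom(self, chrom: str) -> np.ndarray:
        sub = self.dyads[self.dyads["chrom"] == chrom]
        return sub["dyad"].to_numpy()


_FEATURE_LENGTH_PARAMS = {  # lognormal (mean of log, sd of log), minimum length
    "het_TE": (np.log(3000.0), 0.6, 200),
    "eu_TE": (np.log(450.0), 0.5, 60),
    "gene": (np.log(1800.0), 0.5, 300),
}


def _gene_parts(rng: np.random.Generator, chrom: str, start: int, end: int,
                gene_id: str) -> list[tuple]:
    """Split a gene body into alternating exon/intron segments that tile it."""
    length = end - start
    n_exons = 1 + rng.poisson(2.0)
    max_parts = max(1, length // 40)
    n_exons = max(1, min(n_exons, (max_parts + 1) // 2))
    n_seg = 2 * n_exons - 1
    if n_seg == 1:
        return [(chrom, start, end, "exon", gene_id)]
    weights = rng.dirichlet(np.ones(n_seg))
    seg = 40 + np.floor(weights * (length - 40 * n_seg)).astype(int)
    seg[-1] += length - seg.sum()
    out = []
    pos = start
    for i, w in enumerate(seg):
        kind = "exon" if i % 2 == 0 else "intron"
        out.append((chrom, pos, pos + int(w), kind, gene_id))
        pos += int(w)
    return out


def generate_layout(config: SimulationConfig) -> GenomeLayout:
    """Place het_TE / eu_TE / gene features along each chromosome.

    Features are placed sequentially with exponential gaps sized so that the
    expected covered fraction per class matches ``config.feature_fractions``.
    Deterministic given ``config.seed``.
    """
    if not config.chrom_sizes:
        raise InvalidConfigError("config must declare at least one chromosome")
    for chrom, size in config.chrom_sizes.items():
        if size < 10_000:
            raise InvalidConfigError(f"chromosome {chrom!r} shorter than 10 kb")

    rng = np.random.default_rng([config.seed, _STREAM_LAYOUT])
    classes = [c for c in FEATURE_CLASSES if config.feature_fractions.get(c, 0) > 0]
    feat_rows: list[tuple] = []
    part_rows: list[tuple] = []
    if classes:
        fracs = np.array([config.feature_fractions[c] for c in classes])
        mean_len = np.array([np.exp(_FEATURE_LENGTH_PARAMS[c][0] +
                                    _FEATURE_LENGTH_PARAMS[c][1] ** 2 / 2)
                             for c in classes])
        total_frac = fracs.sum()
        # class choice weighted by fraction per unit length
        probs = (fracs / mean_len) / (fracs / mean_len).sum()
        mean_gap = float((probs * mean_len).sum()) * (1 - total_frac) / total_frac
        counters = {c: 0 for c in classes}
        for chrom in sorted(config.chrom_sizes):
            size = config.chrom_sizes[chrom]
            pos = int(rng.exponential(max(mean_gap, 1.0)))
            while True:
                cls = classes[rng.choice(len(classes), p=probs)]
                mu, sigma, min_len = _FEATURE_LENGTH_PARAMS[cls]
                length = max(min_len, int(rng.lognormal(mu, sigma)))
                if pos + length > size:
                    break
                counters[cls] += 1
                fid = f"{cls}_{chrom}_{counters[cls]}"
                strand = "+" if rng.random() < 0.5 else "-"
                feat_rows.append((chrom, pos, pos + length, cls, strand, fid))
                if cls == "gene":
                    part_rows.extend(_gene_parts(rng, chrom, pos, pos + length, fid))
                pos += length + 20 + int(rng.exponential(max(mean_gap, 1.0)))

    features = pd.DataFrame(
        feat_rows, columns=["chrom", "start", "end", "feature_class", "strand",
                            "feature_id"]
    )
    gene_parts = pd.DataFrame(
        part_rows, columns=["chrom", "start", "end", "kind", "gene_id"]
    )
    logger.info("generated layout: %d features (%d gene parts)",
                len(features), len(gene_parts))
    return GenomeLayout(dict(config.chrom_sizes), features, gene_parts)


def simulate_true_nucleosomes(layout: GenomeLayout,
                              config: SimulationConfig) -> TrueNucleosomeMap:
    """Tile each chromosome with 147 bp cores separated by sampled linkers.

    Linker lengths are Normal(linker_length_mean, linker_length_sd) rounded
    and clipped at zero, so consecutive dyads are always >= nucleosome_length
    apart.
    """
    if config.linker_length_mean <= 0:
        raise InvalidConfigError("linker_length_mean must be > 0")
    rng = np.random.default_rng([config.seed, _STREAM_NUCLEOSOMES])
    half = config.nucleosome_length // 2
    rows: list[tuple] = []
    for chrom in sorted(layout.chrom_sizes):
        size = layout.chrom_sizes[chrom]
        feats = layout.features[layout.features["chrom"] == chrom]
        starts = feats["start"].to_numpy()
        ends = feats["end"].to_numpy()
        labels = feats["feature_class"].to_numpy()

        def classify(dyad: int) -> str:
            i = np.searchsorted(starts, dyad, side="right") - 1
            if i >= 0 and dyad < ends[i]:
                return str(labels[i])
            return "intergenic"

        dyad = half + _sample_linker(rng, config)
        while dyad + half < size:
            rows.append((chrom, dyad, classify(dyad)))
            dyad += config.nucleosome_length + _sample_linker(rng, config)
    dyads = pd.DataFrame(rows, columns=["chrom", "dyad", "feature_class"])
    logger.info("placed %d true nucleosomes", len(dyads))
    return TrueNucleosomeMap(dyads, config.nucleosome_length)


def _sample_linker(rng: np.random.Generator, config: SimulationConfig) -> int:
    if config.linker_length_sd == 0:
        return int(round(config.linker_length_mean))
    return max(0, int(round(rng.normal(config.linker_length_mean,
                                       config.linker_length_sd))))


def _sample_lengths(rng: np.random.Generator, config: SimulationConfig,
                    n: int) -> np.ndarray:
    if config.fragment_length_dist is not None:
        lengths = np.asarray(list(config.fragment_length_dist.keys()), int)
        probs = np.asarray(list(config.fragment_length_dist.values()), float)
        return rng.choice(lengths, size=n, p=probs / probs.sum())
    raw = np.rint(rng.normal(config.fragment_length_mean,
                             config.fragment_length_sd, n))
    return np.clip(raw, 50, None).astype(int)


def simulate_fragments(nmap: TrueNucleosomeMap, config: SimulationConfig,
                       n_replicates: int = 2) -> list[pd.DataFrame]:
    """Draw per-replicate MNase fragment sets around the true dyads.

    Each fragment midpoint is its dyad plus rounded Normal(0, positioning_sd)
    jitter (sd per feature class); fragment counts per nucleosome are
    Poisson(coverage_mean).  Replicates use independent sub-seeds.
    Returns one BED-like DataFrame (chrom, start, end) per replicate.
    """
    if n_replicates < 1:
        raise InvalidConfigError("n_replicates must be >= 1")
    dyads = nmap.dyads
    out: list[pd.DataFrame] = []
    sizes = {c: 0 for c in dyads["chrom"].unique()}
    for rep in range(n_replicates):
        rng = np.random.default_rng([config.seed, _STREAM_FRAGMENTS, rep])
        if dyads.empty:
            out.append(pd.DataFrame(columns=["chrom", "start", "end"]))
            continue
        counts = rng.poisson(config.coverage_mean, len(dyads))
        chroms = np.repeat(dyads["chrom"].to_numpy(), counts)
        centers = np.repeat(dyads["dyad"].to_numpy(), counts)
        sds = np.repeat(
            dyads["feature_class"].map(config.positioning_sd_for).to_numpy(float),
            counts,
        )
        jitter = rng.standard_normal(len(centers)) * sds
        mids = np.rint(centers + jitter).astype(int)
        lengths = _sample_lengths(rng, config, len(mids))
        starts = mids - lengths // 2
        ends = starts + lengths
        frame = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        frame = frame[frame["start"] >= 0]
        frame = frame.sort_values(["chrom", "start", "end"], kind="mergesort")
        out.append(frame.reset_index(drop=True))
        logger.info("replicate %d: %d fragments", rep + 1, len(frame))
    del sizes
    return out


def _cytosine_sites(layout: GenomeLayout,
                    config: SimulationConfig) -> pd.DataFrame:
    """Sample cytosine positions/strands/contexts, independent of genotype."""
    rng = np.random.default_rng([config.seed, _STREAM_CYTOSINE_SITES])
    ctx = np.asarray(CONTEXTS)
    probs = np.asarray([config.context_probs[c] for c in CONTEXTS], float)
    rows = []
    for chrom in sorted(layout.chrom_sizes):
        size = layout.chrom_sizes[chrom]
        for strand in ("+", "-"):
            pos = np.nonzero(rng.random(size) < config.cytosine_density)[0]
            contexts = ctx[rng.choice(len(ctx), size=len(pos), p=probs)]
            rows.append(pd.DataFrame({
                "chrom": chrom, "pos": pos, "strand": strand,
                "context": contexts,
            }))
    sites = pd.concat(rows, ignore_index=True)
    return sites.sort_values(["chrom", "pos", "strand"],
                             kind="mergesort").reset_index(drop=True)


def _nearest_dyad_offset(pos: np.ndarray, dyads: np.ndarray) -> np.ndarray:
    """Signed offset of each position from its nearest dyad (inf if none)."""
    if len(dyads) == 0:
        return np.full(len(pos), np.inf)
    idx = np.searchsorted(dyads, pos)
    left = dyads[np.clip(idx - 1, 0, len(dyads) - 1)]
    right = dyads[np.clip(idx, 0, len(dyads) - 1)]
    d_left = pos - left
    d_right = pos - right
    take_left = np.abs(d_left) <= np.abs(d_right)
    return np.where(take_left, d_left, d_right).astype(float)


def simulate_methylome(layout: GenomeLayout, nmap: TrueNucleosomeMap,
                       genotype: str, config: SimulationConfig) -> pd.DataFrame:
    """Simulate per-cytosine bisulfite counts for one genotype.

    Cytosines within +-(nucleosome_length-1)//2 bp of a true dyad methylate at
    core_rate + rotational_amplitude * cos(2*pi*offset/rotational_period)
    (cosine maximum at the dyad); all other cytosines at linker_rate.  Read
    totals are Poisson(coverage_mean) (zero-coverage sites dropped) and
    methylated counts Binomial(total, rate).

    Cytosine positions, strands and contexts are drawn from a
    genotype-independent stream, so all genotypes share the same sites.
    Returns a DataFrame (chrom, pos, strand, context, count_meth, count_total)
    with 0-based positions.
    """
    if genotype not in config.genotype_params:
        raise InvalidConfigError(
            f"unknown genotype {genotype!r}; available: "
            f"{sorted(config.genotype_params)}"
        )
    gi = sorted(config.genotype_params).index(genotype)
    rng = np.random.default_rng([config.seed, _STREAM_METHYLOME, gi])
    sites = _cytosine_sites(layout, config)
    params = config.genotype_params[genotype]
    core = np.array([params[c].core_rate for c in CONTEXTS])
    link = np.array([params[c].linker_rate for c in CONTEXTS])
    amp = np.array([params[c].rotational_amplitude for c in CONTEXTS])
    ctx_code = pd.Categorical(sites["context"], categories=CONTEXTS).codes
    half = (config.nucleosome_length - 1) // 2

    rate = np.empty(len(sites))
    for chrom in sorted(layout.chrom_sizes):
        mask = (sites["chrom"] == chrom).to_numpy()
        offs = _nearest_dyad_offset(sites.loc[mask, "pos"].to_numpy(),
                                    nmap.for_chrom(chrom))
        codes = ctx_code[mask]
        in_core = np.abs(offs) <= half
        r = link[codes].copy()
        r[in_core] = core[codes][in_core] + amp[codes][in_core] * np.cos(
            2 * np.pi * offs[in_core] / config.rotational_period
        )
        rate[mask] = np.clip(r, 0.0, 1.0)

    totals = rng.poisson(config.coverage_mean, len(sites))
    covered = totals > 0
    meth = np.zeros(len(sites), dtype=int)
    meth[covered] = rng.binomial(totals[covered], rate[covered])
    records = sites.assign(count_meth=meth, count_total=totals)[covered]
    records = records.reset_index(drop=True)
    logger.info("simulated %s methylome: %d covered cytosines",
                genotype, len(records))
    return records


def simulate_te_scores(layout: GenomeLayout, config: SimulationConfig
                       ) -> pd.DataFrame:
    """Per-TE CG-methylation fractions and H3K9me2 enrichment scores.

    Heterochromatic TEs get high mCG and high H3K9me2; euchromatic TEs low
    values of both, emulating the two chromatin compartments.
    """
    rng = np.random.default_rng([config.seed, _STREAM_TE_SCORES])
    tes = layout.features[
        layout.features["feature_class"].isin(["het_TE", "eu_TE"])
    ].copy().reset_index(drop=True)
    het = (tes["feature_class"] == "het_TE").to_numpy()
    mcg = np.where(het, rng.uniform(0.3, 0.95, len(tes)),
                   rng.uniform(0.0, 0.15, len(tes)))
    k9 = np.where(het, rng.normal(3.0, 0.5, len(tes)),
                  rng.normal(0.5, 0.3, len(tes)))
    tes["mcg"] = mcg
    tes["h3k9me2"] = k9
    return tes


@dataclass
class DmrStudy:
    """Planted-region benchmark for the DMR caller."""

    records: dict[str, pd.DataFrame]  # genotype -> cytosine records
    te_annotation: pd.DataFrame  # chrom, start, end
    planted: pd.DataFrame  # regions with focal-mutant-exclusive loss
    decoys: pd.DataFrame  # regions lost in both mutants
    wt_label: str = "WT"
    mut_label: str = "cmt2"
    other_label: str = "drm1drm2"


def simulate_dmr_study(seed: int = 0, n_planted: int = 100, n_decoys: int = 100,
                       region_length: int = 150, spacing: int = 400,
                       coverage_mean: float = 20.0, wt_rate: float = 0.25,
                       depleted_rate: float = 0.05,
                       background_rate: float = 0.02,
                       site_spacing: int = 4) -> DmrStudy:
    """Plant mutant-exclusive hypomethylated regions plus shared-loss decoys.

    Regions are 50 bp-grid-aligned CHH-methylated TEs on one chromosome:
    all genotypes methylate them at ``wt_rate`` except that the focal mutant
    drops to ``depleted_rate`` in planted regions and BOTH mutants drop in
    decoy regions.  Between regions methylation is near zero.  CHH sites are
    placed every ``site_spacing`` bp on alternating strands, so every 50 bp
    window carries the same site count (and hence the intended coverage) —
    the benchmark measures the caller, not site-density fluctuations.
    """
    chrom = "chr1"
    n_regions = n_planted + n_decoys
    size = n_regions * spacing + 200
    starts = 100 + spacing * np.arange(n_regions)
    is_planted = np.arange(n_regions) % 2 == 0
    # balance counts exactly
    planted_starts = starts[is_planted][:n_planted]
    decoy_starts = starts[~is_planted][:n_decoys]
    used = np.sort(np.concatenate([planted_starts, decoy_starts]))

    pos = np.arange(1, size, site_spacing)
    strand = np.where(np.arange(len(pos)) % 2 == 0, "+", "-")

    def region_mask(region_starts: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(region_starts, pos, side="right") - 1
        idx = np.clip(idx, 0, max(len(region_starts) - 1, 0))
        if len(region_starts) == 0:
            return np.zeros(len(pos), bool)
        s = region_starts[idx]
        return (pos >= s) & (pos < s + region_length)

    in_planted = region_mask(planted_starts)
    in_decoy = region_mask(decoy_starts)
    in_region = in_planted | in_decoy

    study_rates = {
        "WT": np.where(in_region, wt_rate, background_rate),
        "cmt2": np.where(in_planted | in_decoy,
                         np.where(in_planted, depleted_rate,
                                  depleted_rate),
                         background_rate),
        "drm1drm2": np.where(in_decoy, depleted_rate,
                             np.where(in_planted, wt_rate, background_rate)),
    }
    records = {}
    for gi, (genotype, rate) in enumerate(sorted(study_rates.items())):
        grng = np.random.default_rng([seed, _STREAM_DMR_STUDY, 1, gi])
        totals = grng.poisson(coverage_mean, len(pos))
        covered = totals > 0
        meth = np.zeros(len(pos), int)
        meth[covered] = grng.binomial(totals[covered], rate[covered])
        records[genotype] = pd.DataFrame({
            "chrom": chrom, "pos": pos[covered], "strand": strand[covered],
            "context": "CHH", "count_meth": meth[covered],
            "count_total": totals[covered],
        })
    te = pd.DataFrame({"chrom": chrom, "start": used,
                       "end": used + region_length})
    planted = pd.DataFrame({"chrom": chrom, "start": planted_starts,
                            "end": planted_starts + region_length})
    decoys = pd.DataFrame({"chrom": chrom, "start": decoy_starts,
                           "end": decoy_starts + region_length})
    logger.info("DMR study: %d planted, %d decoy regions, %d cytosines",
                len(planted), len(decoys), len(pos))
    return DmrStudy(records, te, planted, decoys)


def simulate_locus_matrix(n_phased: int = 500, n_flat: int = 500,
                          n_bins: int = 50, bin_size: int = 10,
                          repeat_length: int = 177, core_half: int = 73,
                          high: float = 0.85, low: float = 0.25,
                          noise_sd: float = 0.08,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Dyad-centered methylation matrix mixing phased and flat loci.

    Phased rows alternate between a low nucleosome-core level and a high
    linker level with the nucleosome repeat length; flat rows sit at the
    midpoint.  Gaussian noise (clipped to [0, 1]) is added to every cell.
    Returns (matrix, labels) with labels 1 for phased rows, 0 for flat.
    """
    rng = np.random.default_rng([seed, _STREAM_LOCUS_MATRIX])
    flank = n_bins * bin_size / 2
    centers = (np.arange(n_bins) + 0.5) * bin_size - flank
    wrapped = (centers + repeat_length / 2) % repeat_length - repeat_length / 2
    pattern = np.where(np.abs(wrapped) <= core_half, low, high)
    flat = np.full(n_bins, (high + low) / 2)
    matrix = np.vstack([
        np.tile(pattern, (n_phased, 1)),
        np.tile(flat, (n_flat, 1)),
    ])
    matrix = np.clip(matrix + rng.normal(0, noise_sd, matrix.shape), 0.0, 1.0)
    labels = np.concatenate([np.ones(n_phased, int), np.zeros(n_flat, int)])
    return matrix, labels
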