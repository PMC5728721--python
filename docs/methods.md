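# Methods

This note documents the models, defaults and design choices behind
`nucmeth`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic benchmark does and does not show.

## 1. The synthetic study (`nucmeth.simulate`)

The generator emulates a bisulfite + MNase-seq study of one plant genome in
four genotypes. It is deliberately the *simplest* model with the structure
the analyses exploit; every distributional choice below is an artifact
decision, not an empirical fit.

**Genome layout.** Chromosomes (default one 1 Mb chromosome) are tiled
sequentially with three feature classes — heterochromatic TEs, euchromatic
TEs, genes — with lognormal lengths (medians ≈3 kb, 450 bp, 1.8 kb) and
exponential gaps sized so the expected covered fractions match the
configuration (defaults 0.40 / 0.10 / 0.30). Genes are split into
alternating exon/intron segments (each ≥40 bp) that tile the gene body
exactly.

**Nucleosomes.** True dyads alternate 147 bp cores with linkers drawn from
`Normal(30, 5)` bp, rounded and clipped at zero, giving a ~177 bp repeat
(a typical plant nucleosome repeat length) and guaranteeing dyad spacing
≥147 bp.

**MNase fragments.** Per nucleosome and replicate, `Poisson(coverage_mean)`
fragments (default mean 10) are drawn; each fragment midpoint is the true
dyad plus rounded `Normal(0, positioning_sd)` jitter, with the jitter SD set
per feature class (defaults: het_TE 2 bp, gene 8 bp, eu_TE 15 bp,
intergenic 25 bp — heterochromatic arrays are the best positioned, matching
the compartment where the downstream analyses anchor). Fragment lengths are
a rounded `Normal(147, 8)` (or any supplied discrete distribution); only
length-147 fragments serve as periodicity anchors, so the length
distribution controls anchor yield, not anchor quality. Replicates use
independent sub-seeds of the master seed.

**Methylomes.** Cytosine sites are labels, not sequence: each position on
each strand is a cytosine with probability 0.18, with context probabilities
CG 0.17 / CHG 0.17 / CHH 0.66 (roughly Arabidopsis-like densities). Sites,
strands and contexts are drawn from a genotype-independent stream so all
genotypes share the same sites. A site within ±73 bp of a true dyad
methylates at

    core_rate + rotational_amplitude · cos(2π · offset / 10)

(cosine maximum at the dyad — any fixed phase would do; fixing it makes
tests exact), and at `linker_rate` otherwise. Read totals are
`Poisson(coverage_mean)` (zero-coverage sites dropped); methylated counts
are Binomial. Default per-genotype rates encode the qualitative genotype
structure: mild core depletion in WT/h1, strong core depletion in ddm1,
strong depletion with near-WT linkers in h1ddm1 (e.g. CG core/linker:
WT 0.85/0.90, h1 0.88/0.92, ddm1 0.25/0.45, h1ddm1 0.25/0.85), with
rotational amplitudes 0.04–0.05 in WT/h1, 0.02 in h1ddm1 and exactly 0 in
ddm1 — so the 10 bp periodicity exists in every genotype except the
remodeler mutant, and is attenuated but present in the double mutant.

**What the generator does not emulate:** MNase sequence bias, nucleotide
sequence and real context geometry (CG symmetry, CHG palindromes),
copy-number structure, conversion errors, and mappability. Passing tests
therefore demonstrate that the *analysis chain* recovers planted structure
at realistic noise levels — not that it is robust to every artifact of real
libraries.

**DMR benchmark.** `simulate_dmr_study` plants 100 focal-mutant-exclusive
hypomethylated regions (CHH 0.25 → 0.05) and 100 shared-loss decoys
(both mutants 0.05) as 150 bp, 50 bp-grid-aligned TEs at 20× coverage.
CHH sites are placed deterministically every 4 bp on alternating strands so
every 50 bp window carries ~12 sites (~250 reads): the benchmark measures
the caller, not site-density fluctuations. This matters — with Bernoulli
site placement, rare windows hold 2–3 sites and the *other-mutant*
significance test becomes underpowered, letting an occasional shared-loss
window through as "exclusive". That behavior is a genuine property of
same-alpha exclusivity filters at low coverage and is worth remembering when
applying the caller to sparse data.

## 2. Nucleosome positioning (`nucmeth.nucleosomes`)

The peak caller is intentionally simple: per-bp fragment-midpoint counts are
smoothed with a Gaussian kernel (default bandwidth 15 bp; the density array
is zero-padded so boundary peaks are callable), local maxima become summits,
and each bound is the half-maximum crossing or the flanking density minimum,
whichever is nearer the summit. Externally called peak BEDs can be
substituted at every entry point. Peaks wider than 140 bp are removed
(width exactly 140 is kept).

Classification is replicate-1-anchored: each rep-1 peak takes its *best*
reciprocal overlap (`min` of the two fractional overlaps) over all
overlapping rep-2 peaks. Group boundaries are half-open at the top —
(0.75, 1], (0.50, 0.75], (0.25, 0.50], (0, 0.25] — so a boundary value falls
to the lower group; peaks with no overlap are "other". Symmetrizing
(classifying rep 2 against rep 1 as well) is not done; the rep-1 anchoring
is the documented convention.

The dyad is `round((min start + max end)/2)` over the rep-1 peak and *all*
its overlapping rep-2 peaks (the union-span midpoint). For asymmetric
overlap stacks this differs from the mean of all endpoints, which is exposed
as `method="endpoint_mean"`.

Shared nucleosomes across genotypes match dyads within 20 bp *inclusive*,
greedily by distance, each call used at most once, ties to the leftmost.
Genic nucleosome labels: *exonic* = any (≥1 bp) exon overlap; *intronic* =
entirely inside a single intron; everything else unlabeled. Heterochromatic
TEs are those with mCG > 5%, H3K9me2 in the upper two quintiles (rank-based
quintiles over the supplied set), and length > 30 bp.

## 3. Metaprofiles (`nucmeth.profiles`)

Bins pool methylated/total counts across anchors and report the pooled
fraction (coverage-weighted); an unweighted per-site mean is available as
`weighting="site_mean"`. Strands are combined; symmetric-CG collapsing is
not performed (records stay per-strand as filed — pooling makes a collapse
unnecessary). Nucleosome anchors are unoriented; TSS/gene anchors are
oriented by strand, with minus-strand offsets reflected as `-(offset) - 1`
so the half-open bin grid mirrors exactly. Dyad-scale analyses default to
1 bp bins; coarser (10 bp) bins suit kilobase-flank analyses. RPM tracks
are bin counts × 1e6 / mapped reads. A cytosine inside the flank of several
anchors is pooled once per anchor — the read-anchored convention; note that
this correlates neighboring bins of the *pooled* profile, which is why the
rate-recovery tests use single-sided bins where each read appears once.

## 4. DMR calling (`nucmeth.dmr`)

Windows tile each chromosome from position 0 in fixed, non-overlapping
50 bp steps (the grid phase is a convention; it is not optimized). The
"30% loss" criterion is *relative* — `(f_WT − f_mut)/f_WT > 0.30` — since an
absolute 30-point reading would be unattainable for windows near the 10%
WT floor that the definition explicitly admits. The test is the one-sided
(mutant-lower) Fisher's exact test, computed as the hypergeometric lower
tail via log-gamma (stable far beyond 1e4 totals); a two-sided preference
can be emulated but the loss direction is the scientific question.
Exclusivity re-evaluates all three criteria against the other mutant
(default) or its p-value alone (`exclusivity="significance"`). "Adjacent"
windows are book-ended (gap exactly 0); windows separated by a failing
window stay separate DMRs. No multiple-testing correction is applied by
default (raw p < 0.01); a Benjamini–Hochberg option exists. DMRs are
conventionally required to overlap an annotated TE.

## 5. Rotational periodicity (`nucmeth.periodicity`)

Anchors are fragments of exactly 147 bp, optionally restricted to fragments
fully inside a mask (heterochromatic TEs, genes, CTCF ±1 kb). The fragment
5′ start defines offset 1; orientations are not symmetrized (a symmetrize
step would average the vector with its reverse; with unoriented anchors the
pooled vector is statistically symmetric already). Missing offsets are
imputed with the vector mean before the FFT — this keeps n fixed and adds no
spectral component. The periodogram is raw: mean-centering only, no taper,
no detrending, `power(k) = |DFT_k|²/n` for k = 1..⌊n/2⌋ on the Fourier grid
(no interpolation), reported against period n/k and truncated at 30 bp for
plots. With this one-sided normalization and odd n, Parseval reads
`2·Σ power = n·var`. "A peak at 10 bp" means the maximum falls on a Fourier
period that rounds to 10 (147/15 = 9.8 or 147/14 = 10.5); ties break toward
the smaller period within a 1e-9 relative tolerance so numerically exact
ties survive floating-point rounding.

## 6. SOM clustering (`nucmeth.som`)

A 1×k Kohonen map (default k = 5, 100 epochs, initial learning rate 0.5,
Gaussian neighborhood σ starting at k/2, both decaying linearly; codebook
initialized from sampled rows; all seeded). These hyperparameters are
artifact defaults — the reference heatmap tooling does not report its
settings — and k, epochs and learning rate are exposed. Missing cells are
imputed with column means for training; original missingness is preserved
in the matrix for reporting. Cluster labels are arbitrary: the "phased"
cluster is identified post hoc as the one whose centroid has the largest
peak-to-trough amplitude, never by index. On a 1-D map, adjacent units
share a planted population (two units may split the phased rows); the
amplitude criterion still lands on a phased unit, but consumers wanting a
single phased *set* should merge units above an amplitude threshold.

## 7. Pipeline and reproducibility

All randomness flows from one integer seed through named sub-streams
(layout, nucleosomes, fragments-per-replicate, cytosine sites,
methylome-per-genotype), so any stage can be regenerated independently and
identical configurations give byte-identical outputs; the pipeline manifest
records SHA-256 checksums of every output to make this checkable. Default
problem sizes — 1 Mb genomes (~5,600 nucleosomes, ~2,800 periodicity
anchors), 300–400 kb genomes for positioning/rate/clustering studies, and
200 planted regions for the DMR benchmark — were chosen so each recovery
property is measured with comfortable statistical margin while a full run
stays in the tens of seconds on a laptop core.

## Known limitations

* The peak caller is a kernel-density stand-in, not a reimplementation of
  shape-aware callers (no Laplacian-of-Gaussian shape classes); import
  externally called peaks where shape matters.
* Exclusivity filtering shares the focal test's alpha; at low per-window
  coverage the other-mutant test loses power before the focal one, biasing
  borderline shared losses toward "exclusive" (see §1).
* Genome-scale results from the original biological datasets (tens of
  thousands of nucleosomes and DMRs) require the raw sequencing data and an
  aligner upstream of this package; the synthetic studies here validate the
  method chain, not those genome-wide counts.
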