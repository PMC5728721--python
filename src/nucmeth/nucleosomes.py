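"""Nucleosome peak calling, positioning-reliability classification and dyads.

The workflow mirrors replicate-based MNase-seq positioning analysis:
mononucleosomal fragments (120-180 bp, exclusive) are reduced to midpoint
densities, peaks are called per replicate, width-filtered at 140 bp, and
replicate-one peaks are classified by their best reciprocal overlap with
replicate two into reliability groups 1-4 (25% increments, group 1 = both
overlap fractions > 0.75) plus an "other" group.  Each classified nucleosome
gets a presumptive dyad: the midpoint of the union span of all overlapping
peaks.  Externally called peak BED files can be substituted for the built-in
kernel-density caller.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .errors import InvalidConfigError

logger = logging.getLogger(__name__)

#: group code used for peaks with no replicate overlap
GROUP_OTHER = 0
DEFAULT_GROUP_THRESHOLDS = (0.75, 0.50, 0.25, 0.0)


def filter_fragments(fragments: pd.DataFrame, min_exclusive: int = 120,
                     max_exclusive: int = 180) -> pd.DataFrame:
    """Keep mononucleosomal fragments with min < length < max (both exclusive)."""
    length = fragments["end"] - fragments["start"]
    out = fragments[(length > min_exclusive) & (length < max_exclusive)]
    logger.info("fragment length filter: %d of %d retained",
                len(out), len(fragments))
    return out.reset_index(drop=True)


def call_peaks(fragments: pd.DataFrame, bandwidth: float = 15.0,
               min_density: float = 0.05) -> pd.DataFrame:
    """Call nucleosome peaks from Gaussian-smoothed fragment-midpoint density.

    Local maxima of the smoothed density become summits; each peak's bounds
    are taken at the half-maximum crossing or the flanking density minimum,
    whichever is nearer the summit.  Returns a DataFrame (chrom, start, end,
    summit, height) sorted by position; summits are strictly increasing per
    chromosome.
    """
    if bandwidth <= 0:
        raise InvalidConfigError("bandwidth must be > 0")
    rows: list[tuple] = []
    if len(fragments):
        pad = int(np.ceil(4 * bandwidth)) + 2
        for chrom, grp in fragments.groupby("chrom", sort=True):
            mids = ((grp["start"] + grp["end"]) // 2).to_numpy()
            counts = np.bincount(mids, minlength=int(mids.max()) + 1 + pad)
            density = gaussian_filter1d(counts.astype(float), bandwidth,
                                        truncate=4.0, mode="constant")
            summits, _ = find_peaks(density, height=min_density)
            for i, summit in enumerate(summits):
                left_floor = summits[i - 1] if i > 0 else 0
                right_floor = summits[i + 1] if i + 1 < len(summits) \
                    else len(density) - 1
                left_min = left_floor + int(np.argmin(density[left_floor:summit + 1]))
                right_min = summit + int(np.argmin(density[summit:right_floor + 1]))
                half = density[summit] / 2.0
                below = np.nonzero(density[left_min:summit] < half)[0]
                start = left_min + int(below[-1]) + 1 if len(below) else left_min
                below = np.nonzero(density[summit + 1:right_min + 1] < half)[0]
                end = summit + 1 + int(below[0]) if len(below) else right_min + 1
                rows.append((chrom, start, end, int(summit),
                             float(density[summit])))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit",
                                        "height"])
    logger.info("called %d peaks (bandwidth %.1f bp)", len(peaks), bandwidth)
    return peaks


def filter_peak_width(peaks: pd.DataFrame, max_width: int = 140) -> pd.DataFrame:
    """Drop peaks wider than ``max_width`` bp (width exactly 140 is kept)."""
    width = peaks["end"] - peaks["start"]
    out = peaks[width <= max_width]
    logger.info("width filter (<= %d bp): %d of %d retained",
                max_width, len(out), len(peaks))
    return out.reset_index(drop=True)


def reciprocal_overlap(a, b) -> tuple[float, float]:
    """Overlap of two same-chromosome intervals as fractions of each width.

    ``a``/``b`` expose chrom/start/end (e.g. DataFrame rows or namedtuples).
    The reciprocal overlap used for classification is the minimum of the pair.
    """
    if a["chrom"] != b["chrom"]:
        raise ValueError("intervals on different chromosomes")
    ovl = max(0, min(a["end"], b["end"]) - max(a["start"], b["start"]))
    return ovl / (a["end"] - a["start"]), ovl / (b["end"] - b["start"])


def compute_dyad(member_peaks, method: str = "union_span") -> int:
    """Presumptive dyad from the set of mutually overlapping peaks.

    ``union_span`` (default): mean of the outermost 5'- and 3'-most ends,
    i.e. the midpoint of the union span.  ``endpoint_mean``: mean of all
    member start/end coordinates (differs for asymmetric overlaps).
    """
    if isinstance(member_peaks, pd.DataFrame):
        starts = member_peaks["start"].to_numpy()
        ends = member_peaks["end"].to_numpy()
    else:
        pairs = [(p[0], p[1]) for p in member_peaks]
        if not pairs:
            raise ValueError("empty member set")
        starts = np.array([p[0] for p in pairs])
        ends = np.array([p[1] for p in pairs])
    if len(starts) == 0:
        raise ValueError("empty member set")
    if method == "union_span":
        return int(round((starts.min() + ends.max()) / 2.0))
    if method == "endpoint_mean":
        return int(round(float(np.concatenate([starts, ends]).mean())))
    raise InvalidConfigError(f"unknown dyad method {method!r}")


def _sorted(peaks: pd.DataFrame, label: str) -> pd.DataFrame:
    if not peaks["start"].is_monotonic_increasing:
        logger.info("sorting unsorted %s peaks", label)
        peaks = peaks.sort_values(["chrom", "start", "end"], kind="mergesort")
    return peaks.reset_index(drop=True)


def _trees(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in peaks.groupby("chrom", sort=True):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), i) for i, (s, e) in
            zip(grp.index, zip(grp["start"], grp["end"]))
        )
    return trees


def classify_positioning(peaks_rep1: pd.DataFrame, peaks_rep2: pd.DataFrame,
                         thresholds: Sequence[float] = DEFAULT_GROUP_THRESHOLDS,
                         dyad_method: str = "union_span") -> pd.DataFrame:
    """Assign every replicate-one peak a positioning-reliability group.

    A peak's reciprocal overlap with a replicate-two peak is the minimum of
    the two fractional overlaps; the peak is scored by its best such value
    across all overlapping replicate-two peaks.  Groups are half-open at the
    top: group 1 for > thresholds[0] (0.75), group 2 for > 0.50, group 3 for
    > 0.25, group 4 for > 0, else ``GROUP_OTHER``.  The dyad is computed from
    the replicate-one peak together with ALL overlapping replicate-two peaks.

    Returns a DataFrame (chrom, dyad, group, start, end, best_overlap,
    rep1_start, rep1_end) where start/end is the union span.
    """
    peaks_rep1 = _sorted(peaks_rep1, "replicate-1")
    peaks_rep2 = _sorted(peaks_rep2, "replicate-2")
    trees = _trees(peaks_rep2)
    rows: list[tuple] = []
    for row in peaks_rep1.itertuples(index=False):
        chrom, s1, e1 = row.chrom, int(row.start), int(row.end)
        w1 = e1 - s1
        hits = sorted(trees[chrom].overlap(s1, e1)) if chrom in trees else []
        best = 0.0
        starts, ends = [s1], [e1]
        for hit in hits:
            ovl = min(e1, hit.end) - max(s1, hit.begin)
            frac = min(ovl / w1, ovl / (hit.end - hit.begin))
            best = max(best, frac)
            starts.append(hit.begin)
            ends.append(hit.end)
        group = GROUP_OTHER
        for g, threshold in enumerate(thresholds, start=1):
            if best > threshold:
                group = g
                break
        dyad = compute_dyad(list(zip(starts, ends)), method=dyad_method)
        rows.append((chrom, dyad, group, min(starts), max(ends), best, s1, e1))
    calls = pd.DataFrame(rows, columns=["chrom", "dyad", "group", "start",
                                        "end", "best_overlap", "rep1_start",
                                        "rep1_end"])
    if len(calls):
        counts = calls["group"].value_counts().to_dict()
        logger.info("classified %d peaks; group sizes %s", len(calls), counts)
    return calls


def shared_nucleosomes(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                       max_dist: int = 20) -> pd.DataFrame:
    """Match nucleosomes across genotypes by dyad distance <= max_dist bp.

    Greedy nearest-dyad matching; each call is matched at most once, ties
    broken toward the leftmost dyad.  Returns (chrom, dyad_a, dyad_b,
    distance, index_a, index_b).
    """
    rows: list[tuple] = []
    for chrom in sorted(set(calls_a["chrom"]) & set(calls_b["chrom"])):
        sub_a = calls_a[calls_a["chrom"] == chrom]
        sub_b = calls_b[calls_b["chrom"] == chrom].sort_values("dyad")
        b_dyads = sub_b["dyad"].to_numpy()
        b_index = sub_b.index.to_numpy()
        candidates = []
        for ia, da in zip(sub_a.index, sub_a["dyad"]):
            lo = np.searchsorted(b_dyads, da - max_dist, side="left")
            hi = np.searchsorted(b_dyads, da + max_dist, side="right")
            for j in range(lo, hi):
                candidates.append((abs(int(da) - int(b_dyads[j])), int(da),
                                   int(b_dyads[j]), ia, b_index[j]))
        candidates.sort()
        taken_a: set = set()
        taken_b: set = set()
        for dist, da, db, ia, ib in candidates:
            if ia in taken_a or ib in taken_b:
                continue
            taken_a.add(ia)
            taken_b.add(ib)
            rows.append((chrom, da, db, dist, ia, ib))
    out = pd.DataFrame(rows, columns=["chrom", "dyad_a", "dyad_b", "distance",
                                      "index_a", "index_b"])
    logger.info("matched %d shared nucleosomes (<= %d bp)", len(out), max_dist)
    return out


def classify_genic_nucleosomes(calls: pd.DataFrame,
                               gene_parts: pd.DataFrame) -> pd.Series:
    """Label nucleosome spans as exonic or intronic.

    Exonic: any (>= 1 bp) overlap with an exon.  Intronic: the span lies
    entirely within a single intron and touches no exon.  Everything else is
    unlabeled (NaN).  ``gene_parts`` carries chrom/start/end/kind columns
    with kind in {exon, intron}.
    """
    exon_trees = _trees(gene_parts[gene_parts["kind"] == "exon"])
    intron_trees = _trees(gene_parts[gene_parts["kind"] == "intron"])
    labels = []
    for row in calls.itertuples(index=False):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        if chrom in exon_trees and exon_trees[chrom].overlap(start, end):
            labels.append("exonic")
            continue
        contained = False
        if chrom in intron_trees:
            for hit in intron_trees[chrom].overlap(start, end):
                if hit.begin <= start and end <= hit.end:
                    contained = True
                    break
        labels.append("intronic" if contained else None)
    return pd.Series(labels, index=calls.index, dtype="object")


def filter_heterochromatic_tes(tes: pd.DataFrame, min_mcg: float = 0.05,
                               min_length: int = 30,
                               upper_quintiles: int = 2) -> pd.DataFrame:
    """Select heterochromatic TEs by methylation, H3K9me2 rank and length.

    Keeps TEs with CG methylation fraction > ``min_mcg``, an H3K9me2 score in
    the upper ``upper_quintiles`` quintiles of the supplied set, and length
    strictly greater than ``min_length`` bp.  ``tes`` must carry ``mcg`` and
    ``h3k9me2`` columns; missing scores raise an error naming the TEs.
    """
    missing = tes[tes["mcg"].isna() | tes["h3k9me2"].isna()]
    if len(missing):
        ids = (missing["feature_id"] if "feature_id" in missing
               else missing.index).tolist()
        raise InvalidConfigError(f"missing mCG/H3K9me2 score for TEs: {ids}")
    if len(tes) == 0:
        return tes.copy()
    rank = tes["h3k9me2"].rank(method="first")
    quintile = np.ceil(5.0 * rank / len(tes)).astype(int)
    keep = (
        (tes["mcg"] > min_mcg)
        & (quintile > 5 - upper_quintiles)
        & ((tes["end"] - tes["start"]) > min_length)
    )
    out = tes[keep].reset_index(drop=True)
    logger.info("heterochromatic TE filter: %d of %d retained",
                len(out), len(tes))
    return out
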