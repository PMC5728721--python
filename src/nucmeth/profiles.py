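"""Anchor-centered methylation metaprofiles and coverage tracks.

Methylation fractions are weighted (pooled-count) averages by default:
within each bin, methylated and total read counts are summed over all
cytosines of the requested context across all anchors, and the bin fraction
is the ratio of the pooled sums.  An unweighted per-site mean is available
for comparison.  Anchors may be unoriented points (nucleosome dyads) or
stranded points (TSSs, CTCF motifs); in oriented mode offsets are mirrored
for minus-strand anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, ProfileMismatchError

logger = logging.getLogger(__name__)


@dataclass
class MethylationProfile:
    """Binned, anchor-relative pooled methylation."""

    bin_offsets: np.ndarray  # left edge of each bin, bp relative to anchor
    bin_size: int
    n_meth: np.ndarray
    n_total: np.ndarray
    fraction: np.ndarray  # NaN where a bin has no coverage
    context: str
    label: str = ""
    n_anchors: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": self.bin_offsets,
            "n_meth": self.n_meth.astype(int),
            "n_total": self.n_total.astype(int),
            "fraction": self.fraction,
        })

    @classmethod
    def pool(cls, first: "MethylationProfile",
             second: "MethylationProfile") -> "MethylationProfile":
        """Count-wise pooling of two profiles over the same bins."""
        _check_compatible(first, second)
        n_meth = first.n_meth + second.n_meth
        n_total = first.n_total + second.n_total
        return cls(first.bin_offsets.copy(), first.bin_size, n_meth, n_total,
                   _safe_fraction(n_meth, n_total), first.context,
                   label=first.label,
                   n_anchors=first.n_anchors + second.n_anchors)


def _check_compatible(a: MethylationProfile, b: MethylationProfile) -> None:
    if a.bin_size != b.bin_size or not np.array_equal(a.bin_offsets,
                                                      b.bin_offsets):
        raise ProfileMismatchError("profiles have different bin grids")
    if a.context != b.context:
        raise ProfileMismatchError(
            f"profiles have different contexts ({a.context!r} vs {b.context!r})"
        )


def _safe_fraction(n_meth: np.ndarray, n_total: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_total > 0, n_meth / np.maximum(n_total, 1), np.nan)


def weighted_methylation(records: pd.DataFrame, chrom: str, start: int,
                         end: int, context: str | None = None) -> float:
    """Pooled methylation fraction over an interval (NaN when uncovered)."""
    sel = records[(records["chrom"] == chrom) & (records["pos"] >= start)
                  & (records["pos"] < end)]
    if context is not None:
        sel = sel[sel["context"] == context]
    total = int(sel["count_total"].sum())
    if total == 0:
        return float("nan")
    return float(sel["count_meth"].sum() / total)


def profile_around_anchors(records: pd.DataFrame, anchors: pd.DataFrame,
                           flank: int, bin_size: int = 1,
                           context: str = "CG", oriented: bool = False,
                           weighting: str = "pooled",
                           label: str = "") -> MethylationProfile:
    """Pool methylation counts into offset bins around a set of anchors.

    ``anchors`` carries chrom/pos (and strand when ``oriented``).  Bins tile
    [-flank, flank) with the given width; a cytosine at genomic position p
    lands at offset p - anchor (mirrored as -(offset) - 1 for minus-strand
    anchors in oriented mode, so the half-open grid reflects exactly).
    Cytosines within the flank of several anchors are counted once per
    anchor, as in read-anchored averaging.
    """
    if bin_size <= 0:
        raise InvalidConfigError("bin size must be > 0")
    if flank % bin_size:
        raise InvalidConfigError("flank must be a multiple of the bin size")
    if weighting not in {"pooled", "site_mean"}:
        raise InvalidConfigError(f"unknown weighting {weighting!r}")
    offsets = np.arange(-flank, flank, bin_size)
    n_bins = len(offsets)
    n_meth = np.zeros(n_bins)
    n_total = np.zeros(n_bins)
    frac_sum = np.zeros(n_bins)
    site_count = np.zeros(n_bins)

    recs = records[records["context"] == context]
    by_chrom = {}
    for chrom, grp in recs.groupby("chrom", sort=True):
        order = np.argsort(grp["pos"].to_numpy(), kind="mergesort")
        by_chrom[chrom] = (
            grp["pos"].to_numpy()[order],
            grp["count_meth"].to_numpy()[order],
            grp["count_total"].to_numpy()[order],
        )

    strands = anchors["strand"] if oriented and "strand" in anchors else None
    for k, row in enumerate(anchors.itertuples(index=False)):
        chrom = row.chrom
        if chrom not in by_chrom:
            continue
        pos, meth, total = by_chrom[chrom]
        center = int(row.pos)
        lo = np.searchsorted(pos, center - flank, side="left")
        hi = np.searchsorted(pos, center + flank, side="left")
        if hi <= lo:
            continue
        d = pos[lo:hi] - center
        if strands is not None and strands.iloc[k] == "-":
            d = -d - 1
        idx = (d + flank) // bin_size
        np.add.at(n_meth, idx, meth[lo:hi])
        np.add.at(n_total, idx, total[lo:hi])
        if weighting == "site_mean":
            covered = total[lo:hi] > 0
            np.add.at(frac_sum, idx[covered],
                      meth[lo:hi][covered] / total[lo:hi][covered])
            np.add.at(site_count, idx, covered)

    if weighting == "pooled":
        fraction = _safe_fraction(n_meth, n_total)
    else:
        with np.errstate(invalid="ignore"):
            fraction = np.where(site_count > 0,
                                frac_sum / np.maximum(site_count, 1), np.nan)
    return MethylationProfile(offsets, bin_size, n_meth, n_total, fraction,
                              context, label=label, n_anchors=len(anchors))


def difference_profile(profile_mut: MethylationProfile,
                       profile_wt: MethylationProfile) -> pd.DataFrame:
    """Per-bin mutant-minus-wild-type methylation difference.

    Bins missing in either profile are NaN in the difference.  Raises
    :class:`ProfileMismatchError` when bin grids or contexts differ.
    """
    _check_compatible(profile_mut, profile_wt)
    diff = profile_mut.fraction - profile_wt.fraction
    return pd.DataFrame({"offset": profile_mut.bin_offsets,
                         "difference": diff})


def rpm_normalize(fragments: pd.DataFrame, total_mapped: int,
                  bin_size: int = 10,
                  chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Bin fragment midpoints and scale to reads per million mapped.

    Each bin value is (midpoints in bin) * 1e6 / total_mapped.  Returns a
    bedGraph-shaped DataFrame (chrom, start, end, rpm) covering each
    chromosome up to ``chrom_sizes`` (or the last observed midpoint).
    """
    if total_mapped <= 0:
        raise InvalidConfigError("total_mapped must be > 0")
    if bin_size <= 0:
        raise InvalidConfigError("bin size must be > 0")
    tracks = []
    for chrom, grp in fragments.groupby("chrom", sort=True):
        mids = ((grp["start"] + grp["end"]) // 2).to_numpy()
        size = (chrom_sizes or {}).get(chrom, int(mids.max()) + 1)
        n_bins = int(np.ceil(size / bin_size))
        counts = np.bincount(np.minimum(mids // bin_size, n_bins - 1),
                             minlength=n_bins)
        starts = np.arange(n_bins) * bin_size
        tracks.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": np.minimum(starts + bin_size, size),
            "count": counts,
            "rpm": counts * 1e6 / total_mapped,
        }))
    out = pd.concat(tracks, ignore_index=True) if tracks else pd.DataFrame(
        columns=["chrom", "start", "end", "count", "rpm"])
    logger.info("RPM track: %d bins, %d fragments", len(out), len(fragments))
    return out


def profile_by_expression_decile(records: pd.DataFrame, genes: pd.DataFrame,
                                 decile_table: dict[str, int],
                                 flank: int, bin_size: int = 10,
                                 context: str = "CG",
                                 oriented: bool = True
                                 ) -> dict[int, MethylationProfile]:
    """Anchor profiles partitioned by gene expression decile.

    ``genes`` carries gene_id/chrom/pos(/strand) anchor rows.  Genes missing
    from ``decile_table`` are excluded (a warning logs the count); deciles
    with no genes are absent from the result.
    """
    known = genes["gene_id"].map(decile_table)
    missing = int(known.isna().sum())
    if missing:
        logger.warning("%d genes missing from decile table; excluded", missing)
    profiles: dict[int, MethylationProfile] = {}
    for decile, grp in genes[known.notna()].groupby(known.dropna().astype(int)):
        if grp.empty:
            continue
        profiles[int(decile)] = profile_around_anchors(
            records, grp, flank=flank, bin_size=bin_size, context=context,
            oriented=oriented, label=f"decile_{int(decile)}",
        )
    for d in range(1, 11):
        if d not in profiles:
            logger.info("expression decile %d empty; absent from output", d)
    return profiles
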