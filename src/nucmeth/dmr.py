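"""Window-based calling of mutant-exclusive differentially methylated regions.

The procedure: chromosomes are tiled with non-overlapping 50 bp windows
(grid anchored at position 0) and per-genotype CHH counts are pooled per
window.  A window is a candidate DMR window for a focal mutant when

* wild-type methylation is at least 10% (``min_wt``),
* the relative loss (wt - mut) / wt exceeds 30% (``min_loss``), and
* the loss is significant by a one-sided Fisher's exact test (p < 0.01).

Windows that also satisfy all three criteria against the OTHER mutant are
discarded, making calls exclusive to the focal genotype.  Surviving
book-ended windows are merged into DMRs.  No multiple-testing correction is
applied by default (an optional Benjamini-Hochberg flag exists); called DMRs
are conventionally required to overlap an annotated TE.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import InvalidConfigError

logger = logging.getLogger(__name__)


def fisher_exact_one_sided(meth_wt: int, unmeth_wt: int, meth_mut: int,
                           unmeth_mut: int) -> float:
    """One-sided (mutant-lower) Fisher's exact test p-value.

    Conditional on the table margins, the mutant methylated count follows a
    hypergeometric distribution; the p-value is the lower tail
    P(X <= meth_mut), evaluated through the log-gamma-based hypergeometric
    CDF (stable for totals well beyond 1e4).  A mutant fraction above the
    wild type therefore yields p >= 0.5: an increase is never called a loss.
    """
    counts = (meth_wt, unmeth_wt, meth_mut, unmeth_mut)
    if any(c < 0 for c in counts):
        raise InvalidConfigError("counts must be >= 0")
    n_wt = meth_wt + unmeth_wt
    n_mut = meth_mut + unmeth_mut
    if n_wt == 0 or n_mut == 0:
        raise InvalidConfigError("both group totals must be > 0")
    total = n_wt + n_mut
    k_meth = meth_wt + meth_mut
    return float(stats.hypergeom.cdf(meth_mut, total, k_meth, n_mut))


def window_counts(records_by_genotype: dict[str, pd.DataFrame],
                  window: int = 50, context: str = "CHH",
                  chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Pool per-cytosine counts of one context into fixed windows per genotype.

    Windows tile each chromosome from position 0 in non-overlapping steps of
    ``window`` bp.  Returns one row per window with columns
    ``meth_<genotype>`` / ``total_<genotype>`` and a ``covered_<genotype>``
    flag; windows with zero total coverage in a genotype are flagged False.
    """
    if window <= 0:
        raise InvalidConfigError("window must be > 0")
    if not records_by_genotype:
        raise InvalidConfigError("at least one genotype required")
    chroms: dict[str, int] = dict(chrom_sizes or {})
    for records in records_by_genotype.values():
        sub = records[records["context"] == context]
        for chrom, grp in sub.groupby("chrom"):
            extent = int(grp["pos"].max()) + 1
            chroms[chrom] = max(chroms.get(chrom, 0), extent)

    frames = []
    for chrom in sorted(chroms):
        n_windows = int(np.ceil(chroms[chrom] / window))
        if n_windows == 0:
            continue
        starts = np.arange(n_windows) * window
        frame = pd.DataFrame({"chrom": chrom, "start": starts,
                              "end": starts + window})
        for genotype, records in records_by_genotype.items():
            sub = records[(records["context"] == context)
                          & (records["chrom"] == chrom)]
            idx = sub["pos"].to_numpy() // window
            meth = np.bincount(idx, weights=sub["count_meth"],
                               minlength=n_windows)[:n_windows]
            total = np.bincount(idx, weights=sub["count_total"],
                                minlength=n_windows)[:n_windows]
            frame[f"meth_{genotype}"] = meth.astype(int)
            frame[f"total_{genotype}"] = total.astype(int)
            frame[f"covered_{genotype}"] = total > 0
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    logger.info("pooled %s counts into %d windows of %d bp",
                context, len(out), window)
    return out


def _window_test(windows: pd.DataFrame, wt: str, mut: str, min_wt: float,
                 min_loss: float, alpha: float,
                 p_values: np.ndarray) -> np.ndarray:
    """Vectorized three-criteria window test for one mutant."""
    total_wt = windows[f"total_{wt}"].to_numpy(float)
    total_mut = windows[f"total_{mut}"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_wt = windows[f"meth_{wt}"].to_numpy(float) / total_wt
        f_mut = windows[f"meth_{mut}"].to_numpy(float) / total_mut
        rel_loss = (f_wt - f_mut) / f_wt
    ok = (total_wt > 0) & (total_mut > 0)
    return (ok & (f_wt >= min_wt) & (rel_loss > min_loss)
            & (p_values < alpha))


def _window_p_values(windows: pd.DataFrame, wt: str, mut: str) -> np.ndarray:
    meth_wt = windows[f"meth_{wt}"].to_numpy(int)
    total_wt = windows[f"total_{wt}"].to_numpy(int)
    meth_mut = windows[f"meth_{mut}"].to_numpy(int)
    total_mut = windows[f"total_{mut}"].to_numpy(int)
    p = np.ones(len(windows))
    ok = (total_wt > 0) & (total_mut > 0)
    p[ok] = stats.hypergeom.cdf(meth_mut[ok],
                                total_wt[ok] + total_mut[ok],
                                meth_wt[ok] + meth_mut[ok],
                                total_mut[ok])
    return p


def call_dmrs(windows: pd.DataFrame, wt_label: str, mut_label: str,
              other_mut_label: str, min_wt: float = 0.10,
              min_loss: float = 0.30, alpha: float = 0.01,
              exclusivity: str = "full", fdr: bool = False,
              dependency: str | None = None,
              return_windows: bool = False):
    """Call mutant-exclusive hypomethylated DMRs from pooled windows.

    Candidate windows must pass the methylation floor, relative-loss and
    significance criteria for the focal mutant and must NOT pass for the
    other mutant (``exclusivity="full"``: all three criteria re-evaluated
    against the other mutant; ``"significance"``: its p-value alone).
    Book-ended passing windows (gap exactly 0) merge into one DMR.

    Returns a DataFrame (chrom, start, end, n_windows, min_p, dependency);
    with ``return_windows=True`` also the per-window diagnostics table.
    ``fdr=True`` applies Benjamini-Hochberg to the focal p-values before the
    alpha threshold (off by default).
    """
    for label in (wt_label, mut_label, other_mut_label):
        if f"meth_{label}" not in windows.columns:
            raise InvalidConfigError(
                f"windows carry no counts for genotype {label!r}; "
                "exclusivity cannot be evaluated"
            )
    if exclusivity not in {"full", "significance"}:
        raise InvalidConfigError(f"unknown exclusivity mode {exclusivity!r}")

    p_mut = _window_p_values(windows, wt_label, mut_label)
    p_other = _window_p_values(windows, wt_label, other_mut_label)
    p_for_threshold = p_mut
    if fdr:
        p_for_threshold = stats.false_discovery_control(p_mut, method="bh")
    passes = _window_test(windows, wt_label, mut_label, min_wt, min_loss,
                          alpha, p_for_threshold)
    if exclusivity == "full":
        other_passes = _window_test(windows, wt_label, other_mut_label,
                                    min_wt, min_loss, alpha, p_other)
    else:
        other_passes = p_other < alpha
    selected = passes & ~other_passes

    diag = windows.copy()
    diag["p_value"] = p_mut
    diag["p_other"] = p_other
    diag["passes"] = passes
    diag["exclusive"] = selected

    dmrs = _merge_windows(windows, selected, p_mut,
                          dependency or mut_label)
    logger.info("%d candidate windows, %d exclusive, %d merged DMRs",
                int(passes.sum()), int(selected.sum()), len(dmrs))
    if return_windows:
        return dmrs, diag
    return dmrs


def _merge_windows(windows: pd.DataFrame, selected: np.ndarray,
                   p_values: np.ndarray, dependency: str) -> pd.DataFrame:
    rows = []
    sub = windows[selected].assign(p=p_values[selected])
    for chrom, grp in sub.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        current = None
        for row in grp.itertuples(index=False):
            if current is not None and row.start == current["end"]:
                current["end"] = row.end
                current["n_windows"] += 1
                current["min_p"] = min(current["min_p"], row.p)
            else:
                if current is not None:
                    rows.append(current)
                current = {"chrom": chrom, "start": int(row.start),
                           "end": int(row.end), "n_windows": 1,
                           "min_p": float(row.p)}
        if current is not None:
            rows.append(current)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows",
                                      "min_p"])
    out["dependency"] = dependency
    return out


def require_te_overlap(dmrs: pd.DataFrame,
                       te_annotation: pd.DataFrame) -> pd.DataFrame:
    """Keep DMRs overlapping at least one annotated TE by >= 1 bp."""
    if te_annotation.empty:
        logger.warning("empty TE annotation: all DMRs dropped")
        out = dmrs.iloc[0:0].copy()
        out["te_overlap"] = pd.Series(dtype=bool)
        return out
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in te_annotation.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"])
        )
    keep = [
        row.chrom in trees and bool(trees[row.chrom].overlap(int(row.start),
                                                             int(row.end)))
        for row in dmrs.itertuples(index=False)
    ]
    out = dmrs[np.asarray(keep, bool)].reset_index(drop=True).copy()
    out["te_overlap"] = True
    logger.info("TE-overlap filter: %d of %d DMRs retained", len(out),
                len(dmrs))
    return out


def anchor_dmr_analysis(dmrs: pd.DataFrame,
                        calls: pd.DataFrame) -> tuple[pd.DataFrame,
                                                      pd.DataFrame]:
    """Split DMR-anchored analysis into nucleosomal and non-nucleosomal sets.

    Set A: dyads of group-1 nucleosome calls whose span overlaps a DMR by at
    least 1 bp.  Set B: arithmetic centers (floor of the interval midpoint)
    of DMRs that overlap none of the group 1-4 nucleosome spans.  Both are
    returned as anchor DataFrames (chrom, pos).
    """
    dmr_trees: dict[str, IntervalTree] = {}
    for chrom, grp in dmrs.groupby("chrom"):
        dmr_trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"])
        )
    grouped = calls[calls["group"].isin([1, 2, 3, 4])]
    span_trees: dict[str, IntervalTree] = {}
    for chrom, grp in grouped.groupby("chrom"):
        span_trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"])
        )

    rows_a = []
    group1 = calls[calls["group"] == 1]
    for row in group1.itertuples(index=False):
        if row.chrom in dmr_trees and dmr_trees[row.chrom].overlap(
                int(row.start), int(row.end)):
            rows_a.append((row.chrom, int(row.dyad)))

    rows_b = []
    for row in dmrs.itertuples(index=False):
        if row.chrom in span_trees and span_trees[row.chrom].overlap(
                int(row.start), int(row.end)):
            continue
        rows_b.append((row.chrom, (int(row.start) + int(row.end)) // 2))

    set_a = pd.DataFrame(rows_a, columns=["chrom", "pos"])
    set_b = pd.DataFrame(rows_b, columns=["chrom", "pos"])
    logger.info("DMR anchoring: %d nucleosomal dyads, %d DMR centers",
                len(set_a), len(set_b))
    return set_a, set_b
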