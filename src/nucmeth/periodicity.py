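"""Rotational (~10 bp) methylation periodicity from core-sized fragments.

147 bp fragments — exactly one nucleosome core of DNA — are used as anchors:
for each offset 1..147 from the fragment 5' end, methylated and total read
counts of one context are pooled across all anchors, giving a per-base
average methylation vector.  The raw FFT periodogram of the mean-centered
vector, plotted against period (bp) and truncated at 30 bp, quantifies the
helical-repeat modulation: DNA facing the histone octamer alternates
accessibility every ~10 bp, so rotationally positioned methylation shows a
spectral peak at the Fourier periods bracketing 10 bp (147/15 = 9.8 and
147/14 = 10.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import InvalidConfigError

logger = logging.getLogger(__name__)

CORE_LENGTH = 147


def select_147bp(fragments: pd.DataFrame, mask: pd.DataFrame | None = None,
                 length: int = CORE_LENGTH) -> pd.DataFrame:
    """Keep fragments of exactly ``length`` bp, optionally inside a mask.

    When ``mask`` intervals are given (e.g. heterochromatic TEs, genes), a
    fragment is kept only if its span lies entirely within one mask interval.
    """
    sel = fragments[(fragments["end"] - fragments["start"]) == length]
    if mask is not None and len(sel):
        trees: dict[str, IntervalTree] = {}
        for chrom, grp in mask.groupby("chrom"):
            trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e)) for s, e in zip(grp["start"], grp["end"])
            )
        keep = []
        for row in sel.itertuples(index=False):
            inside = False
            if row.chrom in trees:
                for hit in trees[row.chrom].overlap(int(row.start),
                                                    int(row.end)):
                    if hit.begin <= row.start and row.end <= hit.end:
                        inside = True
                        break
            keep.append(inside)
        sel = sel[np.asarray(keep, bool)]
    logger.info("selected %d anchor fragments of %d bp", len(sel), length)
    return sel.reset_index(drop=True)


@dataclass
class PerBaseVector:
    """Pooled methylation by offset from the fragment 5' end (1..n)."""

    n_meth: np.ndarray
    n_total: np.ndarray
    context: str
    n_anchors: int

    @property
    def fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_total > 0,
                            self.n_meth / np.maximum(self.n_total, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": np.arange(1, len(self.n_meth) + 1),
            "n_meth": self.n_meth.astype(int),
            "n_total": self.n_total.astype(int),
            "fraction": self.fraction,
        })


def per_base_vector(anchors: pd.DataFrame, records: pd.DataFrame,
                    context: str = "CG") -> PerBaseVector:
    """Pool context counts at each of the 147 offsets across all anchors."""
    if len(anchors) == 0:
        raise InvalidConfigError("at least one anchor fragment required")
    lengths = (anchors["end"] - anchors["start"]).unique()
    if len(lengths) != 1:
        raise InvalidConfigError("anchor fragments must share one length")
    n = int(lengths[0])
    n_meth = np.zeros(n)
    n_total = np.zeros(n)
    recs = records[records["context"] == context]
    by_chrom = {}
    for chrom, grp in recs.groupby("chrom", sort=True):
        order = np.argsort(grp["pos"].to_numpy(), kind="mergesort")
        by_chrom[chrom] = (grp["pos"].to_numpy()[order],
                           grp["count_meth"].to_numpy()[order],
                           grp["count_total"].to_numpy()[order])
    for row in anchors.itertuples(index=False):
        if row.chrom not in by_chrom:
            continue
        pos, meth, total = by_chrom[row.chrom]
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.end, side="left")
        if hi <= lo:
            continue
        idx = pos[lo:hi] - int(row.start)
        np.add.at(n_meth, idx, meth[lo:hi])
        np.add.at(n_total, idx, total[lo:hi])
    return PerBaseVector(n_meth, n_total, context, len(anchors))


@dataclass
class PeriodogramResult:
    """One-sided raw periodogram over the Fourier periods n/k."""

    periods: np.ndarray  # n/k for k = 1..floor(n/2), descending
    power: np.ndarray  # |DFT_k|^2 / n
    n: int
    n_imputed: int = 0
    truncation: float = 30.0

    def truncate(self, max_period: float | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Periods and power restricted to periods <= max_period bp."""
        cap = self.truncation if max_period is None else max_period
        keep = self.periods <= cap
        return self.periods[keep], self.power[keep]

    def to_frame(self) -> pd.DataFrame:
        periods, power = self.truncate()
        return pd.DataFrame({"period_bp": periods, "power": power})


def periodogram(vector, max_period: float = 30.0) -> PeriodogramResult:
    """Raw FFT periodogram of a per-base methylation vector.

    Accepts a :class:`PerBaseVector` or a plain array (NaN = missing).
    Missing offsets are imputed with the vector mean (logged), which adds no
    spectral component; the vector is then mean-centered and power(k) =
    |DFT_k|^2 / n is reported for k = 1..floor(n/2) against period n/k.
    For odd n, 2 * sum(power) equals n times the variance of the centered
    vector (Parseval).
    """
    values = vector.fraction if isinstance(vector, PerBaseVector) \
        else np.asarray(vector, float)
    n = len(values)
    if n < 16:
        raise InvalidConfigError("vector must have length >= 16")
    missing = ~np.isfinite(values)
    n_imputed = int(missing.sum())
    if n_imputed == n:
        raise InvalidConfigError("vector has no covered offsets")
    if n_imputed:
        logger.info("imputing %d missing offsets with the vector mean",
                    n_imputed)
        values = np.where(missing, np.nanmean(values), values)
    centered = values - values.mean()
    spectrum = np.fft.rfft(centered)
    k = np.arange(1, n // 2 + 1)
    power = np.abs(spectrum[1:n // 2 + 1]) ** 2 / n
    return PeriodogramResult(n / k, power, n, n_imputed, max_period)


def peak_period(result: PeriodogramResult,
                period_range: tuple[float, float] = (5.0, 30.0)) -> float:
    """Fourier period of maximal power within ``period_range`` (inclusive).

    Ties (within a 1e-9 relative tolerance, so that numerically exact ties
    survive floating-point rounding) break toward the smaller period.
    """
    lo, hi = period_range
    keep = (result.periods >= lo) & (result.periods <= hi)
    if not keep.any():
        raise InvalidConfigError("no Fourier periods in the requested range")
    periods = result.periods[keep]
    power = result.power[keep]
    tied = np.nonzero(power >= power.max() * (1 - 1e-9))[0]
    return float(periods[tied[-1]])  # periods descend with k: last = smallest
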