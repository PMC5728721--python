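"""Readers and writers for the plain-text genomic formats used throughout.

Internal coordinates are 0-based half-open everywhere; converters live at the
file boundary.  The cytosine-report dialect matches Bismark's CX report:
tab-separated ``chrom  pos(1-based)  strand  count_methylated
count_unmethylated  context``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ParseError

logger = logging.getLogger(__name__)

_CX_CONTEXTS = {"CG", "CHG", "CHH"}
_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(frame: pd.DataFrame, path: str | Path,
              columns: list[str] | None = None) -> None:
    """Write intervals as BED (0-based half-open).

    ``columns`` selects optional BED fields beyond chrom/start/end (e.g.
    ["name", "score", "strand"]); missing ones are filled with BED dots.
    """
    cols = ["chrom", "start", "end"] + (columns or [])
    out = frame.reindex(columns=cols).fillna(".")
    out.to_csv(path, sep="\t", header=False, index=False)
    logger.info("wrote %d intervals to %s", len(out), path)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file; extra fields map to name/score/strand."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        dtype={0: str})
    frame.columns = _BED_COLUMNS[: frame.shape[1]]
    frame["start"] = frame["start"].astype(int)
    frame["end"] = frame["end"].astype(int)
    if (frame["end"] <= frame["start"]).any():
        bad = int((frame["end"] <= frame["start"]).idxmax()) + 1
        raise ParseError("interval with end <= start", line_number=bad)
    logger.info("read %d intervals from %s", len(frame), path)
    return frame


def read_bedpe(path: str | Path) -> pd.DataFrame:
    """Read BEDPE mate pairs and collapse each pair to one fragment."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    if frame.shape[1] < 6:
        raise ParseError("BEDPE requires at least 6 columns")
    frame = frame.iloc[:, :6]
    frame.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    if (frame["chrom1"].astype(str) != frame["chrom2"].astype(str)).any():
        raise ParseError("interchromosomal mate pair cannot form a fragment")
    out = pd.DataFrame({
        "chrom": frame["chrom1"].astype(str),
        "start": frame[["start1", "start2"]].min(axis=1).astype(int),
        "end": frame[["end1", "end2"]].max(axis=1).astype(int),
    })
    logger.info("read %d fragments (BEDPE) from %s", len(out), path)
    return out


def write_cx_report(records: pd.DataFrame, path: str | Path) -> None:
    """Write cytosine records as a CX-style report (positions become 1-based)."""
    out = pd.DataFrame({
        "chrom": records["chrom"],
        "pos": records["pos"].astype(int) + 1,
        "strand": records["strand"],
        "count_meth": records["count_meth"].astype(int),
        "count_unmeth": (records["count_total"]
                         - records["count_meth"]).astype(int),
        "context": records["context"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)
    logger.info("wrote %d cytosine records to %s", len(out), path)


def read_cx_report(path: str | Path) -> pd.DataFrame:
    """Read a CX-style cytosine report into 0-based records.

    Returns a DataFrame (chrom, pos, strand, context, count_meth,
    count_total).  Malformed lines raise :class:`ParseError` with the
    offending line number.
    """
    rows = []
    with open(path) as handle:
        for i, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"expected 6 fields, got {len(parts)}",
                                 line_number=i)
            chrom, pos, strand, n_meth, n_unmeth, context = parts
            if context not in _CX_CONTEXTS:
                raise ParseError(f"unknown context token {context!r}",
                                 line_number=i)
            if strand not in {"+", "-"}:
                raise ParseError(f"bad strand {strand!r}", line_number=i)
            try:
                pos_i, meth_i, unmeth_i = int(pos), int(n_meth), int(n_unmeth)
            except ValueError as exc:
                raise ParseError(str(exc), line_number=i) from exc
            if pos_i < 1:
                raise ParseError("positions are 1-based; got "
                                 f"{pos_i}", line_number=i)
            if meth_i < 0 or unmeth_i < 0:
                raise ParseError("negative read count", line_number=i)
            rows.append((chrom, pos_i - 1, strand, context, meth_i,
                         meth_i + unmeth_i))
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                        "count_meth", "count_total"])
    logger.info("read %d cytosine records from %s", len(frame), path)
    return frame


def write_profile_tsv(profile, path: str | Path) -> None:
    """Write a methylation profile as TSV (offset, n_meth, n_total, fraction)."""
    profile.to_frame().to_csv(path, sep="\t", index=False,
                              float_format="%.6g")
    logger.info("wrote profile (%d bins) to %s", len(profile.bin_offsets), path)


def write_bedgraph(track: pd.DataFrame, path: str | Path,
                   value_column: str = "rpm") -> None:
    """Write a per-bin coverage track as bedGraph."""
    out = track[["chrom", "start", "end", value_column]]
    out.to_csv(path, sep="\t", header=False, index=False,
               float_format="%.6g")
    logger.info("wrote %d bedGraph bins to %s", len(out), path)


def write_config(values: Mapping[str, object], path: str | Path) -> None:
    """Write a flat key-value config file (values JSON-encoded)."""
    with open(path, "w") as handle:
        for key in sorted(values):
            handle.write(f"{key} = {json.dumps(values[key])}\n")


def read_config(path: str | Path) -> dict[str, object]:
    """Read a ``key = value`` config file; values parsed as JSON when possible."""
    values: dict[str, object] = {}
    with open(path) as handle:
        for i, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError("expected 'key = value'", line_number=i)
            key, _, raw = line.partition("=")
            raw = raw.strip()
            try:
                values[key.strip()] = json.loads(raw)
            except json.JSONDecodeError:
                values[key.strip()] = raw
    return values


def read_decile_table(path: str | Path) -> dict[str, int]:
    """Read a two-column (gene id, expression decile 1..10) TSV."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["gene_id", "decile"])
    deciles = frame["decile"].astype(int)
    if ((deciles < 1) | (deciles > 10)).any():
        raise ParseError("deciles must be in 1..10")
    return dict(zip(frame["gene_id"].astype(str), deciles))
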