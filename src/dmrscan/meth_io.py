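"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere.  Bismark-style
CpG reports and coverage files are 1-based on disk and are shifted on
read (``assume_one_based=True``, the default).  Collapsed CpG dyads are
anchored at the plus-strand C and span two base pairs when written to
bedGraph.  Chromosome names are compared as exact strings; no ``chr``
prefix normalisation is applied unless explicitly requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = frozenset({"+", "-", "collapsed"})

#: column schema of the on-disk DMR table, fixed for round-tripping
DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "direction",
    "n_cpgs",
    "meth_a",
    "unmeth_a",
    "meth_b",
    "unmeth_b",
    "delta_pct",
    "fet_p",
    "fet_q",
    "het_q_a",
    "het_q_b",
]


class ParseError(ValueError):
    """Malformed input file (wrong columns, bad coordinates, bad counts)."""


@dataclass
class MethCallTable:
    """Per-sample CpG methylation calls.

    ``data`` holds one row per call with columns ``chrom`` (str), ``pos``
    (int, 0-based, dyad anchored at the plus-strand C), ``strand``
    (``+``/``-``/``collapsed``), ``n_meth`` and ``n_unmeth`` (non-negative
    ints).  Rows are kept sorted by (chrom, pos) and, after dyad
    collapsing, are unique per (chrom, pos).
    """

    sample_id: str
    data: pd.DataFrame
    cohort: str | None = None

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "strand", "n_meth", "n_unmeth"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"MethCallTable missing columns: {missing}")
        if (self.data["n_meth"] < 0).any() or (self.data["n_unmeth"] < 0).any():
            raise ValueError("negative methylation counts")
        self.data = (
            self.data[required]
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def coverage(self) -> pd.Series:
        return self.data["n_meth"] + self.data["n_unmeth"]

    @property
    def is_collapsed(self) -> bool:
        return bool((self.data["strand"] == "collapsed").all())

    def percent_methylation(self) -> pd.Series:
        """Per-record percent methylation; NaN where coverage is zero."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.data["n_meth"] / cov
        return pct.where(cov > 0)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class FeatureSet:
    """Named collection of genomic intervals in 0-based half-open coordinates."""

    name: str
    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "label"]))

    def __post_init__(self) -> None:
        for c in ("chrom", "start", "end"):
            if c not in self.data.columns:
                raise ValueError(f"FeatureSet missing column {c!r}")
        if "label" not in self.data.columns:
            self.data = self.data.assign(label="")
        if len(self.data) and (self.data["start"] >= self.data["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        self.data = (
            self.data[["chrom", "start", "end", "label"]]
            .sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )

    @classmethod
    def from_intervals(
        cls, name: str, intervals: Iterable[tuple[str, int, int]]
    ) -> "FeatureSet":
        df = pd.DataFrame(list(intervals), columns=["chrom", "start", "end"])
        return cls(name=name, data=df)

    def intervals(self) -> list[tuple[str, int, int]]:
        return list(
            zip(self.data["chrom"], self.data["start"].astype(int),
                self.data["end"].astype(int))
        )

    def total_bp(self) -> int:
        return int((self.data["end"] - self.data["start"]).sum())

    def __len__(self) -> int:
        return len(self.data)


def read_cpg_report(
    path: str | Path,
    sample_id: str | None = None,
    assume_one_based: bool = True,
    cohort: str | None = None,
) -> MethCallTable:
    """Read a Bismark-style CpG report / coverage table.

    Expected columns: chrom, position, strand, methylated count,
    unmethylated count.  Extra context columns are tolerated and ignored.
    Coverage files that carry a percent column between position and counts
    are not auto-detected; they must be converted first.

    Parameters
    ----------
    assume_one_based
        Treat on-disk positions as 1-based (Bismark convention) and shift
        to the internal 0-based convention.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    records: list[tuple[str, int, str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 5:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=5 columns, got {len(parts)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s = parts[:5]
            if strand not in ("+", "-", "collapsed"):
                raise ParseError(
                    f"{path}: line {lineno}: unknown strand symbol {strand!r}"
                )
            try:
                pos = int(pos_s)
                n_meth = int(meth_s)
                n_unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if n_meth < 0 or n_unmeth < 0:
                raise ParseError(f"{path}: line {lineno}: negative count")
            if assume_one_based:
                pos -= 1
            if pos < 0:
                raise ParseError(f"{path}: line {lineno}: position out of range")
            records.append((chrom, pos, strand, n_meth, n_unmeth))
    df = pd.DataFrame(
        records, columns=["chrom", "pos", "strand", "n_meth", "n_unmeth"]
    )
    if df.empty:
        df = df.astype(
            {"chrom": str, "pos": np.int64, "strand": str,
             "n_meth": np.int64, "n_unmeth": np.int64}
        )
    return MethCallTable(sample_id=sample_id, data=df, cohort=cohort)


def write_cpg_report(
    table: MethCallTable, path: str | Path, one_based: bool = True
) -> None:
    """Write calls in the five-column report layout read_cpg_report accepts."""
    df = table.data.copy()
    if one_based:
        df["pos"] = df["pos"] + 1
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, name: str | None = None) -> FeatureSet:
    """Read a BED3+ file (0-based half-open) into a FeatureSet.

    Overlapping intervals are preserved as given; no merging is applied.
    """
    path = Path(path)
    name = name or path.stem
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: BED needs >=3 columns, got {len(parts)}"
                )
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: invalid interval [{start},{end})"
                )
            label = parts[3] if len(parts) > 3 else ""
            rows.append((chrom, start, end, label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return FeatureSet(name=name, data=df)


def write_bed(features: FeatureSet, path: str | Path) -> None:
    cols = ["chrom", "start", "end"]
    df = features.data
    if (df["label"] != "").any():
        cols = cols + ["label"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(table: MethCallTable, path: str | Path) -> int:
    """Write percent methylation of a collapsed table as bedGraph.

    Each covered dyad becomes one record spanning two base pairs,
    ``pos`` to ``pos + 2``, with value 100 * n_meth / coverage.
    Zero-coverage records are skipped (and counted in the log).
    Returns the number of records written.
    """
    if not table.is_collapsed:
        raise ValueError("write_bedgraph requires a dyad-collapsed table")
    df = table.data
    cov = df["n_meth"] + df["n_unmeth"]
    skipped = int((cov == 0).sum())
    if skipped:
        logger.info("write_bedgraph: skipped %d zero-coverage dyads", skipped)
    keep = df[cov > 0]
    out = pd.DataFrame(
        {
            "chrom": keep["chrom"],
            "start": keep["pos"],
            "end": keep["pos"] + 2,
            "value": 100.0 * keep["n_meth"] / (keep["n_meth"] + keep["n_unmeth"]),
        }
    ).sort_values(["chrom", "start"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False)
    return len(out)


def dmrs_to_frame(dmrs: Sequence) -> pd.DataFrame:
    """Convert a list of DMR records to the canonical table layout."""
    rows = [
        {
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "direction": d.direction,
            "n_cpgs": d.n_cpgs,
            "meth_a": d.meth_a,
            "unmeth_a": d.unmeth_a,
            "meth_b": d.meth_b,
            "unmeth_b": d.unmeth_b,
            "delta_pct": d.delta_pct,
            "fet_p": d.fet_p,
            "fet_q": d.fet_q,
            "het_q_a": d.het_q_a,
            "het_q_b": d.het_q_b,
        }
        for d in dmrs
    ]
    df = pd.DataFrame(rows, columns=DMR_COLUMNS)
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_dmr_table(dmrs: Sequence, path: str | Path) -> None:
    """Write DMRs as a TSV with a fixed header; round-trips via read_dmr_table."""
    df = dmrs_to_frame(dmrs)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dmr_table(path: str | Path) -> list:
    """Read a DMR TSV written by write_dmr_table back into DMR records."""
    from dmrscan.dmr_calling import DMR  # local import avoids cycle

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DMR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing DMR columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DMR(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                direction=str(row.direction),
                n_cpgs=int(row.n_cpgs),
                meth_a=int(row.meth_a),
                unmeth_a=int(row.unmeth_a),
                meth_b=int(row.meth_b),
                unmeth_b=int(row.unmeth_b),
                delta_pct=float(row.delta_pct),
                fet_p=float(row.fet_p),
                fet_q=float(row.fet_q),
                het_q_a=float(row.het_q_a),
                het_q_b=float(row.het_q_b),
            )
        )
    return out
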