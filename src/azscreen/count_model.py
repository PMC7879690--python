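"""Count-table data model and I/O.

Tag-count libraries are held as an integer matrix (contigs x libraries)
together with per-library totals of mapped reads and, when available,
per-contig transcript lengths.  Abundances derive from these in two ways:

* counts per million of the library total (CPM) — depth-normalized only,
  used for the ethylene-treatment libraries where no transcript lengths
  accompany the tag counts;
* reads per kilobase of transcript per million mapped reads (RPKM) —
  depth- and length-normalized, used for the natural-abscission libraries.

All on-disk formats are plain tab-separated text (see `read_count_table`,
`read_sample_sheet`, `read_lengths`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CountTableError",
    "CountTable",
    "SampleSheet",
    "read_count_table",
    "write_count_table",
    "read_lengths",
    "write_lengths",
    "read_sample_sheet",
    "write_sample_sheet",
    "rpkm",
    "rpkm_matrix",
    "cpm_matrix",
    "profile",
]

TISSUES = ("AZ", "P", "M")
TREATMENTS = ("ethylene", "field")


class CountTableError(ValueError):
    """Raised when a count table, sample sheet or lengths file is invalid."""


@dataclass
class CountTable:
    """Integer read counts per contig per library.

    Parameters
    ----------
    counts
        DataFrame of nonnegative integers, index = contig ids,
        columns = library ids.
    library_totals
        Total mapped reads per library.  When ``None`` the column sums are
        used.  Externally supplied totals must be >= the column sums (they
        may include reads mapped to contigs filtered out upstream).
    lengths_bp
        Optional transcript length in bp per contig (required for RPKM).
    """

    counts: pd.DataFrame
    library_totals: pd.Series | None = None
    lengths_bp: pd.Series | None = None
    _totals_external: bool = field(init=False, default=False, repr=False)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate contig ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate library ids: {dups}")
        values = c.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise CountTableError("counts must be integers")
            c = c.astype(np.int64)
            object.__setattr__(self, "counts", c)
        if values.size and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise CountTableError(
                f"negative count at contig {c.index[bad[0]]!r}, "
                f"library {c.columns[bad[1]]!r}"
            )
        colsums = c.sum(axis=0)
        if self.library_totals is None:
            self.library_totals = colsums.astype(np.int64)
        else:
            totals = pd.Series(self.library_totals).reindex(c.columns)
            if totals.isna().any():
                missing = totals.index[totals.isna()].tolist()
                raise CountTableError(f"missing totals for libraries: {missing}")
            if (totals <= 0).any():
                raise CountTableError("library totals must be positive")
            if (totals < colsums).any():
                bad = totals.index[(totals < colsums)].tolist()
                raise CountTableError(
                    f"library totals below column sums for: {bad}"
                )
            self.library_totals = totals.astype(np.int64)
            self._totals_external = True
        if self.lengths_bp is not None:
            lengths = pd.Series(self.lengths_bp).reindex(c.index)
            if lengths.isna().any():
                missing = lengths.index[lengths.isna()].tolist()
                raise CountTableError(f"missing lengths for contigs: {missing}")
            if (lengths < 1).any():
                raise CountTableError("transcript lengths must be >= 1 bp")
            self.lengths_bp = lengths.astype(np.int64)

    @property
    def contig_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def library_ids(self) -> pd.Index:
        return self.counts.columns

    def subset(self, contigs: Iterable[str]) -> "CountTable":
        """Restrict to the given contigs (order preserved)."""
        idx = pd.Index(contigs)
        lengths = None if self.lengths_bp is None else self.lengths_bp.loc[idx]
        return CountTable(self.counts.loc[idx], self.library_totals, lengths)


@dataclass
class SampleSheet:
    """Per-library design metadata.

    One row per library: tissue (AZ, P or M), stage in days after
    pollination, treatment (``ethylene`` with an hours-post-treatment time
    point, or ``field`` without one).
    """

    data: pd.DataFrame  # index library_id; tissue, stage_dap, treatment, time_h

    def __post_init__(self) -> None:
        df = self.data
        required = {"tissue", "stage_dap", "treatment", "time_h"}
        missing = required - set(df.columns)
        if missing:
            raise CountTableError(f"sample sheet missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            raise CountTableError("duplicate library ids in sample sheet")
        bad_tissue = set(df["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise CountTableError(f"unknown tissues: {sorted(bad_tissue)}")
        bad_treat = set(df["treatment"]) - set(TREATMENTS)
        if bad_treat:
            raise CountTableError(f"unknown treatments: {sorted(bad_treat)}")
        eth = df["treatment"] == "ethylene"
        if df.loc[eth, "time_h"].isna().any():
            raise CountTableError("ethylene libraries require time_h")
        if df.loc[~eth, "time_h"].notna().any():
            raise CountTableError("field libraries must not set time_h")
        design = df[["tissue", "stage_dap", "treatment", "time_h"]]
        if design.duplicated().any():
            dup = design[design.duplicated()].iloc[0].tolist()
            raise CountTableError(f"duplicate design cell: {dup}")
        self.data = df.assign(
            stage_dap=df["stage_dap"].astype(int),
            time_h=pd.array(df["time_h"], dtype="Int64"),
        )

    @property
    def library_ids(self) -> pd.Index:
        return self.data.index

    def validate_against(self, table: CountTable) -> None:
        """Check that table libraries and sheet libraries coincide."""
        sheet_ids = set(self.data.index)
        table_ids = set(table.library_ids)
        if sheet_ids != table_ids:
            raise CountTableError(
                f"sample sheet / count table mismatch: "
                f"only in sheet {sorted(sheet_ids - table_ids)}, "
                f"only in table {sorted(table_ids - sheet_ids)}"
            )

    def select(
        self,
        tissue: str | None = None,
        stage_dap: int | None = None,
        treatment: str | None = None,
        time_h: int | None = None,
    ) -> pd.DataFrame:
        df = self.data
        if tissue is not None:
            df = df[df["tissue"] == tissue]
        if stage_dap is not None:
            df = df[df["stage_dap"] == stage_dap]
        if treatment is not None:
            df = df[df["treatment"] == treatment]
        if time_h is not None:
            df = df[df["time_h"] == time_h]
        return df

    def library(
        self,
        tissue: str,
        stage_dap: int,
        treatment: str,
        time_h: int | None = None,
    ) -> str:
        """Return the single library id of a design cell, or raise.

        A missing design cell is an error, never an imputed zero: silently
        zero-filling a missing library would corrupt the screen.
        """
        rows = self.select(tissue, stage_dap, treatment, time_h)
        if len(rows) == 0:
            raise CountTableError(
                f"no library for design cell "
                f"({tissue}, {stage_dap} DAP, {treatment}, t={time_h})"
            )
        if len(rows) > 1:
            raise CountTableError(
                f"ambiguous design cell ({tissue}, {stage_dap}, {treatment}, "
                f"t={time_h}): {rows.index.tolist()}"
            )
        return rows.index[0]


# ---------------------------------------------------------------------------
# I/O — all plain TSV, UTF-8

def read_count_table(path: str | Path, totals_path: str | Path | None = None) -> CountTable:
    """Read a count matrix from TSV (first column contig_id, header = library ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise CountTableError(f"{path}: need a contig_id column plus >= 1 library")
    df = df.set_index(df.columns[0])
    df.index.name = "contig_id"
    try:
        counts = df.apply(pd.to_numeric).astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise CountTableError(f"{path}: non-integer cell ({exc})") from exc
    if not df.apply(pd.to_numeric).eq(counts).all().all():
        raise CountTableError(f"{path}: non-integer count cell")
    totals = None
    if totals_path is not None:
        tdf = pd.read_csv(totals_path, sep="\t")
        totals = pd.Series(
            tdf.iloc[:, 1].to_numpy(), index=tdf.iloc[:, 0].astype(str)
        )
    return CountTable(counts, totals)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", lineterminator="\n")


def read_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    lengths = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    return lengths.astype(np.int64)


def write_lengths(lengths: pd.Series, path: str | Path) -> None:
    out = lengths.rename("length_bp")
    out.index.name = "contig_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    if "library_id" not in df.columns:
        raise CountTableError(f"{path}: sample sheet needs a library_id column")
    df = df.set_index("library_id")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# Abundance

def rpkm(table: CountTable, contig: str, library: str) -> float:
    """RPKM = count * 1e9 / (length_bp * library_total)."""
    if table.lengths_bp is None:
        raise CountTableError("RPKM requires transcript lengths")
    count = int(table.counts.at[contig, library])
    length = int(table.lengths_bp.at[contig])
    total = int(table.library_totals.at[library])
    if total <= 0:
        raise CountTableError(f"library {library!r} has non-positive total")
    return count * 1e9 / (length * total)


def rpkm_matrix(table: CountTable) -> pd.DataFrame:
    """RPKM for every contig x library."""
    if table.lengths_bp is None:
        raise CountTableError("RPKM requires transcript lengths")
    c = table.counts.to_numpy(dtype=float)
    lengths = table.lengths_bp.to_numpy(dtype=float)[:, None]
    totals = table.library_totals.to_numpy(dtype=float)[None, :]
    return pd.DataFrame(
        c * 1e9 / (lengths * totals),
        index=table.contig_ids,
        columns=table.library_ids,
    )


def cpm_matrix(table: CountTable) -> pd.DataFrame:
    """Counts per million of the library total."""
    c = table.counts.to_numpy(dtype=float)
    totals = table.library_totals.to_numpy(dtype=float)[None, :]
    return pd.DataFrame(
        c * 1e6 / totals, index=table.contig_ids, columns=table.library_ids
    )


def profile(
    table: CountTable,
    sheet: SampleSheet,
    contig: str,
    tissue: str,
    stage_dap: int | None,
    treatment: str,
) -> pd.Series:
    """Ordered abundance vector for one contig under a design selector.

    Ethylene selections are ordered by hours of treatment, field selections
    by stage (DAP).  Values are RPKM when lengths are available, otherwise
    counts per million.  The selector must match at least two libraries.
    """
    rows = sheet.select(tissue=tissue, stage_dap=stage_dap, treatment=treatment)
    if len(rows) < 2:
        raise CountTableError(
            f"selector ({tissue}, {stage_dap}, {treatment}) matches "
            f"{len(rows)} libraries; need >= 2"
        )
    if treatment == "ethylene":
        rows = rows.sort_values("time_h")
        keys = rows["time_h"].astype(int)
    else:
        rows = rows.sort_values("stage_dap")
        keys = rows["stage_dap"].astype(int)
    abundance = rpkm_matrix(table) if table.lengths_bp is not None else cpm_matrix(table)
    values = abundance.loc[contig, rows.index]
    values.index = keys.to_numpy()
    values.name = contig
    return values
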