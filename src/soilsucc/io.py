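"""Readers, writers and validation for OTU tables, sample metadata and
environmental covariates.

File dialect: UTF-8 tab-separated text, ``#`` comment lines ignored, first
column is the identifier.  OTU tables may be stored samples-as-rows or
OTUs-as-rows; in memory they are always samples x OTUs.

Grid convention: quadrat ``row``/``col`` are 0-based and (0, 0) is a plot's
south-west corner.  The convention is arbitrary but must be fixed so the
torus-translation null is reproducible; writers record it in output headers.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("sample_id", "plot_id", "row", "col", "stage")

GRID_CONVENTION = "row/col 0-based; (0,0) = plot south-west corner"


class ValidationError(ValueError):
    """Raised when an input file violates the design contract."""


@dataclass
class OtuTable:
    """A samples x OTUs matrix of non-negative integer read counts.

    Parameters
    ----------
    sample_ids, otu_ids
        Ordered, unique identifiers for rows and columns.
    counts
        Integer array of shape ``(len(sample_ids), len(otu_ids))``.
    domain_label
        Free label for the marker domain, e.g. ``"bacteria"`` or ``"fungi"``.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    domain_label: str = ""
    # derived tables (e.g. a dominant-OTU subset) may leave a sample with no
    # reads of the retained OTUs; input tables must not
    allow_empty_samples: bool = False

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            frac, _ = np.modf(counts)
            if np.any(frac != 0):
                i, j = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    f"non-integer count at (sample={self.sample_ids[i]}, "
                    f"OTU={self.otu_ids[j]}): {counts[i, j]}"
                )
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at (sample={self.sample_ids[i]}, "
                f"OTU={self.otu_ids[j]}): {counts[i, j]}"
            )
        depths = counts.sum(axis=1)
        if counts.size and not self.allow_empty_samples and depths.min() == 0:
            bad = [s for s, d in zip(self.sample_ids, depths) if d == 0]
            raise ValidationError(f"sample(s) with zero total reads: {bad}")
        self.counts = counts

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def depths(self) -> np.ndarray:
        """Per-sample total reads."""
        return self.counts.sum(axis=1)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def relative_abundance(self) -> np.ndarray:
        """counts / per-sample depth; rows sum to 1 (all-zero rows stay 0)."""
        depths = self.depths[:, None]
        return np.divide(self.counts, depths, where=depths > 0,
                         out=np.zeros(self.counts.shape, dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.otu_ids)

    def select_otus(self, otu_ids: list[str]) -> "OtuTable":
        idx = {o: j for j, o in enumerate(self.otu_ids)}
        cols = [idx[o] for o in otu_ids]
        return OtuTable(list(self.sample_ids), list(otu_ids),
                        self.counts[:, cols], self.domain_label,
                        allow_empty_samples=True)


@dataclass
class EnvTable:
    """Per-sample environmental covariates (all numeric, complete cases)."""

    data: pd.DataFrame  # index sample_id, numeric columns

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample identifier in env table: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate covariate name: {dup!r}")
        if self.data.isna().any().any():
            col = self.data.columns[self.data.isna().any()][0]
            raise ValidationError(f"missing value in covariate {col!r}")
        for col in self.data.columns:
            if np.ptp(self.data[col].to_numpy()) == 0:
                warnings.warn(f"covariate {col!r} has zero variance", stacklevel=2)

    @property
    def covariates(self) -> list[str]:
        return list(self.data.columns)

    def aligned_to(self, table: OtuTable) -> pd.DataFrame:
        """Rows reordered to the OTU table's sample order."""
        missing = [s for s in table.sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"env table missing sample(s): {missing}")
        return self.data.loc[table.sample_ids]


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str})


def read_otu_table(path, orientation: str = "samples_as_rows",
                   domain_label: str = "") -> OtuTable:
    """Read a TSV count table and validate it.

    ``orientation`` says how the file is laid out; the returned table is
    always samples x OTUs.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    if orientation == "otus_as_rows":
        df = df.T
    sample_ids = [str(s) for s in df.index]
    otu_ids = [str(o) for o in df.columns]
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        try:
            values = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric count in {path}: {exc}") from None
    return OtuTable(sample_ids, otu_ids, values, domain_label=domain_label)


def write_otu_table(table: OtuTable, path, header_comments: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        table.to_dataframe().to_csv(fh, sep="\t")


def read_metadata(path, expected_shape: tuple[int, int] | None = None) -> pd.DataFrame:
    """Read sample metadata and verify the quadrat design.

    Each plot's (row, col) set must form a full rectangle; by default the
    rectangle extent is inferred per plot from the maximum index seen
    (``expected_shape`` pins it explicitly).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    return validate_metadata(df, expected_shape=expected_shape)


def validate_metadata(df: pd.DataFrame,
                      expected_shape: tuple[int, int] | None = None) -> pd.DataFrame:
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"metadata missing column(s): {missing_cols}")
    df = df.loc[:, list(METADATA_COLUMNS)].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["row"] = df["row"].astype(int)
    df["col"] = df["col"].astype(int)
    _check_unique(list(df["sample_id"]), "sample")
    dup = df.duplicated(subset=["plot_id", "row", "col"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate quadrat cell (plot={r.plot_id}, row={r.row}, col={r.col})"
        )
    stage_per_plot = df.groupby("plot_id")["stage"].nunique()
    if (stage_per_plot > 1).any():
        bad = stage_per_plot[stage_per_plot > 1].index[0]
        raise ValidationError(f"plot {bad!r} maps to more than one stage")
    for plot, grp in df.groupby("plot_id"):
        if expected_shape is None:
            n_rows = grp["row"].max() + 1
            n_cols = grp["col"].max() + 1
        else:
            n_rows, n_cols = expected_shape
        want = {(r, c) for r in range(n_rows) for c in range(n_cols)}
        have = set(zip(grp["row"], grp["col"]))
        absent = sorted(want - have)
        if absent:
            raise ValidationError(
                f"plot {plot!r} is not a full {n_rows}x{n_cols} rectangle; "
                f"missing (row, col): {absent}"
            )
        extra = sorted(have - want)
        if extra:
            raise ValidationError(f"plot {plot!r} has cells outside the rectangle: {extra}")
    return df.reset_index(drop=True)


def write_metadata(df: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {GRID_CONVENTION}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_env_table(path) -> EnvTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError):
            raise ValidationError(f"non-numeric value in covariate {col!r}") from None
    return EnvTable(df)


def write_env_table(env: EnvTable, path) -> None:
    env.data.to_csv(path, sep="\t", index_label="sample_id")
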