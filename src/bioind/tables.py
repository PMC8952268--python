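"""Core data containers and I/O for amplicon abundance tables and reactor metadata.

The central objects are :class:`AbundanceTable` (samples x ASVs, read counts
or per-sample relative abundances), :class:`TaxonomyTable` (ASV -> ranks) and
:class:`SampleMetadata` (per-sample reactor, day, hydraulic retention time
(HRT) and process parameters).  The module also provides rarefaction,
relative-abundance closure, the sampling-interval bookkeeping used to label
samples as HRT8/HRT2, and carbon-mole (C-mol) process-parameter derivations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sampling intervals (days, closed on both ends) used to stratify the run.
INTERVALS: tuple[tuple[int, int], ...] = ((0, 50), (51, 100), (101, 140), (141, 211))

#: Class labels attached to the first and last sampling interval.
HRT8 = "HRT8"
HRT2 = "HRT2"
LABELED_INTERVALS: Mapping[tuple[int, int], str] = {INTERVALS[0]: HRT8, INTERVALS[3]: HRT2}

#: Carbon atoms per molecule for C-mol accounting.
CARBON_ATOMS: Mapping[str, int] = {
    "lactate": 3,
    "acetate": 2,
    "C4": 4,  # n-butyrate
    "C6": 6,  # n-caproate
    "C8": 8,  # n-caprylate
    "xylose": 5,
}

#: Required metadata columns (process parameters may contain NaN for missing).
METADATA_COLUMNS: tuple[str, ...] = (
    "sample_id", "reactor", "day", "hrt",
    "conc_lactate", "conc_C4", "conc_C6", "conc_C8",
    "prod_C4", "prod_C6", "prod_C8",
    "yield_C4", "yield_C6", "yield_C8",
)


class TableError(ValueError):
    """Raised on malformed abundance/metadata inputs."""


@dataclass
class AbundanceTable:
    """Samples x ASVs abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with ASV ids as columns; entries are
        non-negative read counts (``mode="counts"``) or per-sample relative
        abundances summing to one (``mode="relative"``).
    mode:
        Either ``"counts"`` or ``"relative"``.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise TableError(f"unknown mode {self.mode!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise TableError(f"duplicate sample ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise TableError(f"duplicate ASV ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if values.size and (values < 0).any():
            raise TableError("negative abundance entries")
        if self.mode == "relative":
            sums = values.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
            if bad.size:
                raise TableError(
                    f"relative rows must sum to 1: {list(self.data.index[bad])}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)], self.mode)

    def feature_matrix(self, asv_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Feature DataFrame restricted to *asv_ids* (zero-filled if absent).

        Returned as a plain DataFrame because a column subset of a relative
        table no longer sums to one and so is not an :class:`AbundanceTable`.
        """
        if asv_ids is None:
            return self.data.astype(float).copy()
        return self.data.reindex(columns=list(asv_ids), fill_value=0.0).astype(float)


@dataclass
class TaxonomyTable:
    """ASV -> taxonomic ranks (phylum..genus), ``"unclassified"`` where unknown."""

    data: pd.DataFrame

    RANKS = ("phylum", "class", "order", "family", "genus")

    def __post_init__(self) -> None:
        missing = [r for r in self.RANKS if r not in self.data.columns]
        if missing:
            raise TableError(f"taxonomy missing ranks: {missing}")

    def genus(self, asv_id: str) -> str:
        if asv_id not in self.data.index:
            return "unclassified"
        return str(self.data.loc[asv_id, "genus"])

    def covers(self, table: AbundanceTable) -> list[str]:
        """Return ASV ids of *table* absent from this taxonomy."""
        return [a for a in table.asv_ids if a not in self.data.index]


@dataclass
class SampleMetadata:
    """Per-sample reactor/day/HRT and process-parameter table.

    Wraps a DataFrame with the canonical columns (:data:`METADATA_COLUMNS`)
    plus derived ``interval`` and ``hrt_label`` columns once
    :func:`assign_interval_and_label` has run.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise TableError(f"metadata missing columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            raise TableError("duplicate sample ids in metadata")
        if (self.frame["hrt"] <= 0).any():
            raise TableError("hrt must be positive")
        quant = self.frame[[c for c in METADATA_COLUMNS if c.startswith(("conc", "prod", "yield"))]]
        if (quant.to_numpy(dtype=float) < -1e-12).any():
            raise TableError("negative process-parameter values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def for_reactor(self, reactor: str) -> "SampleMetadata":
        return SampleMetadata(self.frame[self.frame["reactor"] == reactor].reset_index(drop=True))

    def labeled(self) -> "SampleMetadata":
        """Samples in the HRT8 (0-50 d) and HRT2 (141-211 d) intervals."""
        f = assign_interval_and_label(self).frame
        return SampleMetadata(f[f["hrt_label"].notna()].reset_index(drop=True))


@dataclass(frozen=True)
class CarbonSpec:
    """Carbon atoms per molecule for each compound, used for C-mol conversion."""

    atoms: Mapping[str, int] = field(default_factory=lambda: dict(CARBON_ATOMS))

    def __post_init__(self) -> None:
        for compound, n in self.atoms.items():
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise TableError(f"carbon count for {compound} must be a positive integer")

    def to_cmol(self, compound: str, mmol: float) -> float:
        """Convert an amount in mmol of *compound* to mmol C."""
        if compound not in self.atoms:
            raise TableError(f"unknown compound {compound!r}")
        return mmol * self.atoms[compound]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep(fmt: str) -> str:
    if fmt == "tsv":
        return "\t"
    if fmt == "csv":
        return ","
    raise TableError(f"unknown format {fmt!r}")


def read_abundance_table(path: str | Path, format: str = "tsv") -> AbundanceTable:
    """Read a samples x ASVs table; header row of ASV ids, first column sample ids.

    Mode is inferred: all-integer entries are read counts; rows summing to ~1
    are relative abundances.  A table that is neither is rejected with the
    offending row named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(format), index_col=0)
    if df.shape[0] == 0:
        raise TableError("no samples")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    values = df.to_numpy(dtype=float)
    if np.allclose(values, np.round(values)) and (values.sum(axis=1) > 1.5).any():
        return AbundanceTable(df.astype(int), "counts")
    sums = values.sum(axis=1)
    if np.all(np.abs(sums - 1.0) <= 1e-6):
        return AbundanceTable(df.astype(float), "relative")
    if np.allclose(values, np.round(values)):
        return AbundanceTable(df.astype(int), "counts")
    bad = df.index[int(np.argmax(np.abs(sums - 1.0)))]
    raise TableError(f"ambiguous table mode: row {bad!r} is neither counts nor relative")


def write_abundance_table(table: AbundanceTable, path: str | Path, format: str = "tsv") -> None:
    table.data.to_csv(Path(path), sep=_sep(format), index_label="sample_id")


def read_taxonomy_table(path: str | Path, format: str = "tsv") -> TaxonomyTable:
    df = pd.read_csv(Path(path), sep=_sep(format), index_col=0)
    df.index = df.index.astype(str)
    return TaxonomyTable(df)


def write_taxonomy_table(table: TaxonomyTable, path: str | Path, format: str = "tsv") -> None:
    table.data.to_csv(Path(path), sep=_sep(format), index_label="asv_id")


def read_metadata(path: str | Path, format: str = "tsv") -> SampleMetadata:
    df = pd.read_csv(Path(path), sep=_sep(format))
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path, format: str = "tsv") -> None:
    meta.frame.to_csv(Path(path), sep=_sep(format), index=False)


# ---------------------------------------------------------------------------
# Rarefaction and closure
# ---------------------------------------------------------------------------

def rarefy(table: AbundanceTable, depth: int, seed: int = 42) -> AbundanceTable:
    """Subsample every sample to *depth* reads without replacement.

    Each row is drawn from a multivariate hypergeometric distribution over its
    reads, so per-sample totals are conserved exactly at *depth*.  Samples with
    fewer than *depth* reads are dropped with a warning.
    """
    if table.mode != "counts":
        raise TableError("rarefaction requires a counts table")
    if depth <= 0:
        raise TableError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    counts = table.data.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    if not keep.all():
        dropped = list(table.data.index[~keep])
        logger.warning("dropping %d samples below depth %d: %s", len(dropped), depth, dropped)
    rows = []
    for row, total in zip(counts[keep], totals[keep]):
        if total == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    out = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=table.data.index[keep],
        columns=table.data.columns,
    )
    return AbundanceTable(out, "counts")


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Close each sample's counts to relative abundances (rows sum to one)."""
    values = table.data.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise TableError(f"all-zero sample(s): {list(table.data.index[zero])}")
    rel = pd.DataFrame(values / sums[:, None], index=table.data.index, columns=table.data.columns)
    return AbundanceTable(rel, "relative")


# ---------------------------------------------------------------------------
# Process-parameter derivations
# ---------------------------------------------------------------------------

def derive_productivity(concentration: float, hrt: float) -> float:
    """Volumetric productivity (mmol C L^-1 d^-1) of a semi-continuous reactor.

    At steady state a reactor fed and drawn at volume V/HRT per day turns a
    product concentration c (mmol C L^-1) into a removal rate c/HRT, so the
    dilution form ``productivity = concentration / HRT`` applies.
    """
    if hrt <= 0:
        raise TableError("hrt must be positive")
    if concentration < 0:
        raise TableError("concentration must be non-negative")
    return concentration / hrt


def derive_yield(product_cmol: float, substrate_consumed_cmol: float) -> float:
    """C-mol product per C-mol substrate consumed (dimensionless)."""
    if substrate_consumed_cmol <= 0:
        raise TableError("substrate consumption must be positive")
    if product_cmol < 0:
        raise TableError("product amount must be non-negative")
    return product_cmol / substrate_consumed_cmol


def interval_of(day: float) -> tuple[int, int]:
    """The closed sampling interval containing *day*; errors outside 0-211 d."""
    for lo, hi in INTERVALS:
        if lo <= day <= hi:
            return (lo, hi)
    raise TableError(f"day {day} outside the 0-211 d schedule")


def assign_interval_and_label(meta: SampleMetadata) -> SampleMetadata:
    """Attach ``interval`` (e.g. ``"0-50"``) and ``hrt_label`` columns.

    Labels ``HRT8``/``HRT2`` are attached only to samples in the first
    (0-50 d) and last (141-211 d) intervals; other samples get no label.
    """
    frame = meta.frame.copy()
    intervals, labels = [], []
    for day in frame["day"]:
        lo, hi = interval_of(float(day))
        intervals.append(f"{lo}-{hi}")
        labels.append(LABELED_INTERVALS.get((lo, hi)))
    frame["interval"] = intervals
    frame["hrt_label"] = labels
    return SampleMetadata(frame)
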