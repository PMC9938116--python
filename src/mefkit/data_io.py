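"""Reading, validation and alignment of the three tabular inputs.

The pipeline works on three tables:

* an abundance table (plots x genera, integer stem counts),
* a genus-level trait table (genera x traits, real values with missingness),
* plot metadata (coordinates, forest-type label, plot area).

All identifiers are strings; the canonical internal ordering is
lexicographic by identifier so that results do not depend on the row order
of the input files.  Plot-level filtering (minimum stem diameter, plot-size
bounds) is assumed to have happened upstream, during assembly of the
inventory database.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mefkit")

#: Trait kinds supported by :class:`TraitTable`.
CONTINUOUS = "continuous"
BINARY = "binary"

#: Numeric coding of binary traits: 1 = no, 2 = yes.
BINARY_CODES = (1.0, 2.0)

_NA_VALUES = ["", "NA", "NaN", "nan"]


class ValidationError(ValueError):
    """An input table violates one of its declared invariants."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifiers: {dups}")


@dataclass
class AbundanceTable:
    """Plot-by-genus stem counts.

    ``counts`` is a DataFrame indexed by plot id with genus ids as columns.
    Counts are non-negative integers and every plot must hold at least one
    stem: observed relative abundances and metacommunity priors are both
    derived from this table.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        _check_unique(c.index, "plot")
        _check_unique(c.columns, "genus")
        if not np.issubdtype(np.asarray(c.values).dtype, np.number):
            raise ValidationError("abundance table contains non-numeric cells")
        vals = c.to_numpy()
        if np.any(~np.isfinite(vals)):
            raise ValidationError("abundance table contains missing/non-finite cells")
        if np.any(vals < 0):
            bad = c.index[np.any(vals < 0, axis=1)].tolist()
            raise ValidationError(f"negative counts in plots {bad}")
        if np.any(np.abs(vals - np.round(vals)) > 1e-9):
            raise ValidationError("abundance counts must be integers")
        self.counts = c.astype(np.int64)
        self.counts.index.name = None
        self.counts.columns.name = None
        totals = self.counts.sum(axis=1)
        if (totals <= 0).any():
            empty = totals.index[totals <= 0].tolist()
            raise ValidationError(f"plots with zero total count: {empty}")

    @property
    def plot_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def genus_ids(self) -> pd.Index:
        return self.counts.columns

    def __eq__(self, other) -> bool:  # convenience for round-trip tests
        return isinstance(other, AbundanceTable) and self.counts.equals(other.counts)


@dataclass
class TraitTable:
    """Genus-by-trait values with a missingness mask.

    ``values`` is indexed by genus id with trait ids as columns; missing
    cells are NaN.  ``kinds`` maps each trait to ``"continuous"`` or
    ``"binary"``; binary traits use the coding 1 = no, 2 = yes.  ``units``
    is free-text per trait (empty string where not declared).
    """

    values: pd.DataFrame
    kinds: pd.Series | None = None
    units: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        _check_unique(v.index, "genus")
        _check_unique(v.columns, "trait")
        self.values = v.astype(float)
        self.values.index.name = None
        self.values.columns.name = None
        if self.kinds is None:
            self.kinds = pd.Series(
                {t: self._infer_kind(self.values[t]) for t in v.columns}
            )
        else:
            self.kinds = pd.Series(self.kinds).reindex(v.columns)
            if self.kinds.isna().any():
                missing = self.kinds.index[self.kinds.isna()].tolist()
                raise ValidationError(f"no kind declared for traits {missing}")
            bad = ~self.kinds.isin([CONTINUOUS, BINARY])
            if bad.any():
                raise ValidationError(
                    f"unknown trait kinds: {self.kinds[bad].to_dict()}"
                )
        if self.units is None:
            self.units = pd.Series("", index=v.columns)
        else:
            self.units = pd.Series(self.units).reindex(v.columns).fillna("")
        for t in self.binary_traits:
            col = self.values[t].dropna()
            if not col.isin(BINARY_CODES).all():
                bad_vals = sorted(set(col[~col.isin(BINARY_CODES)]))
                raise ValidationError(
                    f"binary trait {t!r} has values outside {{1, 2}}: {bad_vals}"
                )

    @staticmethod
    def _infer_kind(col: pd.Series) -> str:
        obs = col.dropna()
        if len(obs) and obs.isin(BINARY_CODES).all():
            return BINARY
        return CONTINUOUS

    @property
    def genus_ids(self) -> pd.Index:
        return self.values.index

    @property
    def trait_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def binary_traits(self) -> list[str]:
        return [t for t in self.values.columns if self.kinds[t] == BINARY]

    @property
    def continuous_traits(self) -> list[str]:
        return [t for t in self.values.columns if self.kinds[t] == CONTINUOUS]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def is_complete(self) -> bool:
        return not self.values.isna().any().any()


@dataclass
class PlotMetadata:
    """Per-plot coordinates, forest type and area.

    ``table`` is indexed by plot id with columns ``latitude``, ``longitude``
    (decimal degrees), ``forest_type`` (categorical label) and ``area_ha``.
    """

    table: pd.DataFrame
    forest_type_labels: tuple[str, ...] = ()

    REQUIRED = ("latitude", "longitude", "forest_type", "area_ha")

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "plot")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"plot metadata missing column {col!r}")
        lat = t["latitude"].astype(float)
        lon = t["longitude"].astype(float)
        if ((lat < -90) | (lat > 90)).any():
            raise ValidationError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValidationError("longitude outside [-180, 180]")
        if (t["area_ha"].astype(float) <= 0).any():
            raise ValidationError("plot area must be positive")
        if t["forest_type"].isna().any():
            raise ValidationError("missing forest_type labels")
        if not self.forest_type_labels:
            self.forest_type_labels = tuple(sorted(t["forest_type"].unique()))
        else:
            unknown = set(t["forest_type"]) - set(self.forest_type_labels)
            if unknown:
                raise ValidationError(
                    f"forest types outside declared label set: {sorted(unknown)}"
                )

    @property
    def plot_ids(self) -> pd.Index:
        return self.table.index


def _sep_for(path: str, dialect: str | None) -> str:
    if dialect in ("csv", "tsv"):
        return "," if dialect == "csv" else "\t"
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_abundance_table(path, dialect: str | None = None) -> AbundanceTable:
    """Read a wide plot-by-genus count table (first column = plot id)."""
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0,
                     na_values=_NA_VALUES, keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"malformed numeric cell in column {col!r}, rows {bad.tolist()[:5]}"
            )
    return AbundanceTable(df)


def write_abundance_table(table: AbundanceTable, path, dialect: str | None = None) -> None:
    table.counts.to_csv(path, sep=_sep_for(path, dialect), index_label="plot_id")


def read_trait_table(path, dialect: str | None = None,
                     kinds=None, units=None) -> TraitTable:
    """Read a genus-by-trait table (first column = genus id, NaN/'NA' missing)."""
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0,
                     na_values=_NA_VALUES, keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"malformed numeric cell in trait {col!r}, rows {bad.tolist()[:5]}"
            )
        df[col] = coerced
    return TraitTable(df, kinds=kinds, units=units)


def write_trait_table(table: TraitTable, path, dialect: str | None = None) -> None:
    table.values.to_csv(path, sep=_sep_for(path, dialect), index_label="genus_id",
                        na_rep="NA", float_format="%.12g")


def read_plot_metadata(path, dialect: str | None = None,
                       forest_type_labels: tuple[str, ...] = ()) -> PlotMetadata:
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0,
                     na_values=_NA_VALUES, keep_default_na=False)
    df.index = df.index.astype(str)
    return PlotMetadata(df, forest_type_labels=forest_type_labels)


def write_plot_metadata(meta: PlotMetadata, path, dialect: str | None = None) -> None:
    meta.table.to_csv(path, sep=_sep_for(path, dialect), index_label="plot_id",
                      float_format="%.12g")


@dataclass
class AlignedDataset:
    """Bundle of the three tables on consistent, lexicographically sorted ids.

    ``prior_only_genera`` lists genera that carry counts but no trait
    information at all: they still contribute to observed relative
    abundances and to metacommunity priors, but they enter trait-constraint
    matrices with selection-neutral (prior-mean) trait values.
    """

    abundance: AbundanceTable
    traits: TraitTable
    metadata: PlotMetadata
    prior_only_genera: tuple[str, ...] = ()
    dropped_genera: tuple[str, ...] = ()
    dropped_plots: tuple[str, ...] = ()

    @property
    def plot_ids(self) -> pd.Index:
        return self.abundance.plot_ids

    @property
    def genus_ids(self) -> pd.Index:
        return self.abundance.genus_ids


def align_dataset(abund: AbundanceTable, traits: TraitTable,
                  meta: PlotMetadata) -> AlignedDataset:
    """Intersect plot/genus id sets across the three tables and sort them.

    Genera present only in the trait table are dropped (with a warning).
    Genera with counts but no observed trait value at all are kept for
    priors and observed abundances but flagged as ``prior_only_genera``.
    The operation is idempotent.
    """
    plots = sorted(set(abund.plot_ids) & set(meta.plot_ids))
    if not plots:
        raise ValidationError("no plots shared between abundance table and metadata")
    genera = sorted(abund.genus_ids)

    dropped_plots = tuple(sorted(
        (set(abund.plot_ids) | set(meta.plot_ids)) - set(plots)))
    extra_trait_genera = sorted(set(traits.genus_ids) - set(genera))
    if extra_trait_genera:
        warnings.warn(
            f"dropping {len(extra_trait_genera)} genera present only in the "
            f"trait table: {extra_trait_genera[:10]}", stacklevel=2)
    if dropped_plots:
        warnings.warn(f"dropping plots missing from one table: {list(dropped_plots)[:10]}",
                      stacklevel=2)

    counts = abund.counts.loc[plots, genera]
    nonzero = counts.sum(axis=1) > 0
    if not nonzero.all():
        warnings.warn(f"dropping empty plots after alignment: "
                      f"{counts.index[~nonzero].tolist()}", stacklevel=2)
        counts = counts.loc[nonzero]
        plots = counts.index.tolist()
        dropped_plots = tuple(sorted(set(dropped_plots) | set(nonzero.index[~nonzero])))

    trait_values = traits.values.reindex(genera)
    no_trait = trait_values.isna().all(axis=1)
    prior_only = tuple(trait_values.index[no_trait])
    if prior_only:
        logger.info("genera with counts but no trait data (prior-only): %s",
                    list(prior_only)[:10])

    aligned_traits = TraitTable(trait_values, kinds=traits.kinds.copy(),
                                units=traits.units.copy())
    aligned_meta = PlotMetadata(meta.table.loc[plots].copy(),
                                forest_type_labels=meta.forest_type_labels)
    return AlignedDataset(
        abundance=AbundanceTable(counts),
        traits=aligned_traits,
        metadata=aligned_meta,
        prior_only_genera=prior_only,
        dropped_genera=tuple(extra_trait_genera),
        dropped_plots=dropped_plots,
    )


def file_checksum(path) -> str:
    """SHA-256 of a file, for run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
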