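"""Data model, I/O and occurrence tabulation for predator scat diet records.

Gross scat analysis (GSA) treats each scat (fecal sample) as the sampling
unit. A scat carries a set of prey taxa identified from undigested remains;
a taxon found several times in the same scat still counts once (presence).
Two occurrence summaries are derived per (river, year) group:

* ``pct_scats`` (%S): percent of the group's scats containing the taxon.
  Sums above 100 when scats hold multiple taxa.
* ``pct_records`` (%R): the taxon's share of all prey-item records in the
  group. Sums to 100 and serves as the diet-composition proportion vector
  used downstream for niche breadth and trophic level.

Isotope samples (per-scat delta-15N vs AIR, delta-13C vs VPDB) and the prey
reference table (fractional trophic level and maximum total length per
taxon) are carried as plain pandas DataFrames behind light wrappers.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ScatRecord",
    "ScatCollection",
    "OccurrenceTable",
    "PreyReference",
    "read_scats",
    "write_scats",
    "read_isotopes",
    "tabulate_occurrences",
    "filter_prey_by_length",
    "incidence_matrix",
]

SCAT_COLUMNS = ("scat_id", "river", "year", "taxon")
ISOTOPE_COLUMNS = ("scat_id", "river", "year", "d15N", "d13C")
PREY_COLUMNS = ("taxon", "family", "ftl", "max_total_length_mm", "ftl_source")


class SchemaError(ValueError):
    """An input table is missing required columns, rows, or consistency."""


@dataclass(frozen=True)
class ScatRecord:
    """One scat: its group labels and the set of prey taxa found in it.

    ``items`` holds unique taxon codes; construct via :meth:`from_items`
    to collapse duplicates (with a warning) instead of raising.
    ``contaminated`` flags scats excluded from isotope analyses only —
    they remain valid GSA sampling units.
    """

    scat_id: str
    river: str
    year: int
    items: tuple[str, ...] = ()
    contaminated: bool = False

    def __post_init__(self) -> None:
        if self.year <= 0:
            raise ValueError(f"scat {self.scat_id!r}: year must be positive, got {self.year}")
        if len(set(self.items)) != len(self.items):
            raise ValueError(
                f"scat {self.scat_id!r}: duplicate taxon in items; use ScatRecord.from_items"
            )

    @classmethod
    def from_items(
        cls,
        scat_id: str,
        river: str,
        year: int,
        items: Iterable[str],
        contaminated: bool = False,
    ) -> "ScatRecord":
        items = list(items)
        unique = tuple(dict.fromkeys(items))  # order-preserving dedup
        if len(unique) != len(items):
            warnings.warn(
                f"scat {scat_id!r}: {len(items) - len(unique)} duplicate taxon "
                "record(s) collapsed to presence",
                stacklevel=2,
            )
        return cls(scat_id, river, year, unique, contaminated)

    @property
    def group(self) -> tuple[str, int]:
        return (self.river, self.year)


@dataclass
class ScatCollection:
    """An ordered collection of scats, grouped by (river, year)."""

    records: list[ScatRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.scat_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate scat_id(s): {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ScatRecord]:
        return iter(self.records)

    def groups(self) -> list[tuple[str, int]]:
        """Distinct (river, year) keys, sorted."""
        return sorted({r.group for r in self.records})

    def group_records(self, river: str, year: int) -> list[ScatRecord]:
        return [r for r in self.records if r.river == river and r.year == year]

    def subset(self, river: str, year: int) -> "ScatCollection":
        return ScatCollection(self.group_records(river, year))

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame; scats with no items get one row with empty taxon."""
        rows = []
        for r in self.records:
            if r.items:
                for t in r.items:
                    rows.append((r.scat_id, r.river, r.year, t, r.contaminated))
            else:
                rows.append((r.scat_id, r.river, r.year, "", r.contaminated))
        return pd.DataFrame(rows, columns=list(SCAT_COLUMNS) + ["contaminated"])


def write_scats(collection: ScatCollection, path: str | Path) -> None:
    collection.to_frame().to_csv(path, index=False)


def read_scats(path: str | Path) -> ScatCollection:
    """Read a long-format scat CSV (scat_id,river,year,taxon[,contaminated]).

    Rows sharing a scat_id are one scat; duplicate (scat_id, taxon) rows are
    collapsed to presence with a warning. An empty or blank taxon cell means
    the scat yielded no identifiable items.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"scat_id": str, "river": str, "taxon": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty") from exc
    missing = [c for c in SCAT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: header only, no scat rows")
    try:
        df["year"] = df["year"].astype(int)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: non-integer year value") from exc
    if "contaminated" not in df.columns:
        df["contaminated"] = False
    df["contaminated"] = (
        df["contaminated"].map(_parse_bool).astype(bool)
    )
    df["taxon"] = df["taxon"].fillna("").str.strip()

    records: list[ScatRecord] = []
    for scat_id, sub in df.groupby("scat_id", sort=False):
        for col in ("river", "year", "contaminated"):
            if sub[col].nunique() > 1:
                raise SchemaError(
                    f"{path}: scat {scat_id!r} has conflicting {col} values"
                )
        items = [t for t in sub["taxon"] if t]
        records.append(
            ScatRecord.from_items(
                str(scat_id),
                str(sub["river"].iloc[0]),
                int(sub["year"].iloc[0]),
                items,
                bool(sub["contaminated"].iloc[0]),
            )
        )
    return ScatCollection(records)


def _parse_bool(value: object) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return bool(value)


@dataclass
class OccurrenceTable:
    """Per-(group, taxon) occurrence counts and percentages.

    ``per_taxon`` columns: river, year, taxon, n_records, pct_scats,
    pct_records (full precision). ``per_group`` columns: river, year,
    n_scats, total_records, n_taxa. Display rounding to one decimal is
    applied only in :meth:`to_display`.
    """

    per_taxon: pd.DataFrame
    per_group: pd.DataFrame

    def counts(self, river: str, year: int) -> dict[str, int]:
        sub = self._group(river, year)
        return dict(zip(sub["taxon"], sub["n_records"].astype(int)))

    def proportions(self, river: str, year: int) -> dict[str, float]:
        """Diet-composition proportions (pct_records / 100), full precision."""
        sub = self._group(river, year)
        return dict(zip(sub["taxon"], sub["pct_records"] / 100.0))

    def group_summary(self, river: str, year: int) -> pd.Series:
        sub = self.per_group
        row = sub[(sub["river"] == river) & (sub["year"] == year)]
        if row.empty:
            raise KeyError(f"no group ({river!r}, {year})")
        return row.iloc[0]

    def to_display(self) -> pd.DataFrame:
        out = self.per_taxon.copy()
        out["pct_scats"] = out["pct_scats"].round(1)
        out["pct_records"] = out["pct_records"].round(1)
        return out

    def _group(self, river: str, year: int) -> pd.DataFrame:
        sub = self.per_taxon[
            (self.per_taxon["river"] == river) & (self.per_taxon["year"] == year)
        ]
        if sub.empty:
            raise KeyError(f"no group ({river!r}, {year})")
        return sub


def tabulate_occurrences(collection: ScatCollection) -> OccurrenceTable:
    """Tabulate counts, %S and %R per taxon within each (river, year) group.

    Groups whose scats contain no identifiable items are omitted with a
    warning (no denominator for %R).
    """
    if not collection.records:
        raise SchemaError("cannot tabulate an empty scat collection")
    taxon_rows = []
    group_rows = []
    for river, year in collection.groups():
        recs = collection.group_records(river, year)
        n_scats = len(recs)
        counts = Counter(t for r in recs for t in r.items)
        total = sum(counts.values())
        if total == 0:
            warnings.warn(
                f"group ({river!r}, {year}) has {n_scats} scat(s) but no prey "
                "records; omitted from occurrence table",
                stacklevel=2,
            )
            continue
        for taxon in sorted(counts):
            c = counts[taxon]
            taxon_rows.append(
                (river, year, taxon, c, 100.0 * c / n_scats, 100.0 * c / total)
            )
        group_rows.append((river, year, n_scats, total, len(counts)))
    per_taxon = pd.DataFrame(
        taxon_rows,
        columns=["river", "year", "taxon", "n_records", "pct_scats", "pct_records"],
    )
    per_group = pd.DataFrame(
        group_rows, columns=["river", "year", "n_scats", "total_records", "n_taxa"]
    )
    return OccurrenceTable(per_taxon, per_group)


@dataclass
class PreyReference:
    """Prey lookup: fractional trophic level and maximum total length per taxon.

    FTL values come from a versioned CSV (no live database queries); a taxon
    with missing FTL is excluded from trophic-level computations downstream.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PREY_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"prey reference missing column(s) {missing}")
        if self.table["taxon"].duplicated().any():
            dupes = self.table.loc[self.table["taxon"].duplicated(), "taxon"].tolist()
            raise SchemaError(f"prey reference has duplicate taxa: {dupes}")
        ftl = self.table["ftl"]
        bad = self.table.loc[ftl.notna() & (ftl < 1), "taxon"].tolist()
        if bad:
            raise ValueError(f"FTL must be >= 1; offending taxa: {bad}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PreyReference":
        df = pd.read_csv(path, dtype={"taxon": str, "family": str, "ftl_source": str})
        return cls(df)

    def ftl(self, taxon: str) -> float | None:
        row = self.table[self.table["taxon"] == taxon]
        if row.empty or pd.isna(row["ftl"].iloc[0]):
            return None
        return float(row["ftl"].iloc[0])

    def ftl_map(self) -> dict[str, float]:
        sub = self.table[self.table["ftl"].notna()]
        return dict(zip(sub["taxon"], sub["ftl"].astype(float)))

    def taxa(self) -> list[str]:
        return self.table["taxon"].tolist()


def filter_prey_by_length(
    reference: PreyReference, min_length_mm: float
) -> PreyReference:
    """Keep taxa whose maximum total length is >= the threshold (inclusive).

    Mirrors the candidate-prey rule that the predator takes fish above a
    minimum body size. Taxa with missing length are retained with a warning
    rather than silently dropped.
    """
    if min_length_mm < 0:
        raise ValueError("min_length_mm must be >= 0")
    tab = reference.table
    lengths = tab["max_total_length_mm"]
    keep = lengths.isna() | (lengths >= min_length_mm)
    for taxon in tab.loc[lengths.isna(), "taxon"]:
        warnings.warn(
            f"taxon {taxon!r} has no max_total_length_mm; retained despite "
            f"length filter at {min_length_mm} mm",
            stacklevel=2,
        )
    return PreyReference(tab[keep].reset_index(drop=True))


def read_isotopes(path: str | Path) -> pd.DataFrame:
    """Read per-scat isotope values (scat_id,river,year,d15N,d13C).

    d13C of biological material should be negative (vs VPDB); non-negative
    values trigger a warning, not a rejection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"scat_id": str, "river": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty") from exc
    missing = [c for c in ISOTOPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: header only, no sample rows")
    df["year"] = df["year"].astype(int)
    if not np.isfinite(df["d15N"]).all():
        raise SchemaError(f"{path}: non-finite d15N value(s)")
    n_pos = int((df["d13C"] >= 0).sum())
    if n_pos:
        warnings.warn(
            f"{n_pos} sample(s) with d13C >= 0 permil; unusual for biological "
            "material but retained",
            stacklevel=2,
        )
    return df


def incidence_matrix(records: Sequence[ScatRecord]) -> pd.DataFrame:
    """Binary scat x taxon presence matrix (rows ordered as the records)."""
    taxa = sorted({t for r in records for t in r.items})
    mat = np.zeros((len(records), len(taxa)), dtype=np.int8)
    col = {t: i for i, t in enumerate(taxa)}
    for i, r in enumerate(records):
        for t in r.items:
            mat[i, col[t]] = 1
    return pd.DataFrame(mat, index=[r.scat_id for r in records], columns=taxa)
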