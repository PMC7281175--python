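"""Tabular containers and delimited-text I/O for the pipeline.

Three table kinds flow through the analysis:

* :class:`PeakTable` — GC-MS peak intensities, analytes (rows) by biological
  samples (columns), with a sample→group design (e.g. W = wild-type liver,
  P = precancerous, T = tumor).
* :class:`GeneTable` — FPKM gene expression, same layout.
* :class:`IsotopologueTable` — long-format mass-isotopologue peak areas
  (metabolite, mass shift M+k, sample, area).

Missing cells are kept as NaN and never silently coerced to zero; downstream
imputation is an explicit step. Group labels are arbitrary strings — the
W/P/T trio is a default, not a hard-coded triple.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "GeneTable",
    "IsotopologueTable",
    "SchemaError",
    "DesignError",
    "ValidationError",
    "read_design",
    "read_table",
    "write_results",
    "read_results",
]


class SchemaError(ValueError):
    """Malformed table structure (dimensions, headers, duplicate keys)."""


class DesignError(ValueError):
    """Sample/group design does not match the table."""


class ValidationError(ValueError):
    """Table values violate an invariant (e.g. negative intensity)."""


def _check_design(sample_ids: Sequence[str], group_of: Mapping[str, str]) -> dict:
    missing = [s for s in sample_ids if s not in group_of]
    if missing:
        raise DesignError(f"samples missing from design: {missing}")
    return {s: str(group_of[s]) for s in sample_ids}


@dataclasses.dataclass
class PeakTable:
    """Analyte × sample intensity matrix with a group design.

    ``values`` is a pandas DataFrame indexed by analyte id with one column
    per sample; ``group_of`` maps every sample column to its group label.
    ``retention_time`` (minutes per analyte) is optional.
    """

    values: pd.DataFrame
    group_of: dict[str, str]
    retention_time: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise SchemaError("duplicate analyte ids")
        if self.values.columns.has_duplicates:
            raise SchemaError("duplicate sample ids")
        self.group_of = _check_design(self.values.columns, self.group_of)
        vals = self.values.to_numpy()
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValidationError("negative intensities are not allowed")
        if self.retention_time is not None:
            self.retention_time = self.retention_time.reindex(self.values.index)

    # -- convenience ------------------------------------------------------
    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix of the samples belonging to ``group``."""
        cols = self.samples_in(group)
        if not cols:
            raise DesignError(f"no samples in group {group!r}")
        return self.values[cols]

    def require_min_group_size(self, n: int = 2) -> None:
        for g in self.groups:
            if len(self.samples_in(g)) < n:
                raise DesignError(f"group {g!r} has fewer than {n} samples")

    def subset(self, analyte_ids: Sequence[str]) -> "PeakTable":
        rt = None
        if self.retention_time is not None:
            rt = self.retention_time.loc[list(analyte_ids)]
        return dataclasses.replace(
            self, values=self.values.loc[list(analyte_ids)], retention_time=rt
        )


class GeneTable(PeakTable):
    """FPKM gene × sample matrix; same invariants as :class:`PeakTable`."""


@dataclasses.dataclass
class IsotopologueTable:
    """Long-format isotopologue areas with per-metabolite carbon counts.

    ``records`` has columns (metabolite, mass_shift, sample, area); at most
    one record per (metabolite, mass_shift, sample). Mass shifts must not
    exceed the metabolite's carbon count.
    """

    records: pd.DataFrame
    n_carbons: dict[str, int]
    group_of: dict[str, str] = dataclasses.field(default_factory=dict)

    REQUIRED = ("metabolite", "mass_shift", "sample", "area")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise SchemaError(f"isotopologue table missing columns: {missing}")
        rec = self.records.copy()
        rec["mass_shift"] = rec["mass_shift"].astype(int)
        rec["area"] = rec["area"].astype(float)
        if (rec["area"].dropna() < 0).any():
            raise ValidationError("negative peak areas are not allowed")
        if (rec["mass_shift"] < 0).any():
            raise ValidationError("negative mass shifts are not allowed")
        for met, sub in rec.groupby("metabolite"):
            if met not in self.n_carbons:
                raise SchemaError(f"no carbon count declared for {met!r}")
            if int(sub["mass_shift"].max()) > self.n_carbons[met]:
                raise ValidationError(
                    f"{met!r}: mass shift exceeds {self.n_carbons[met]} carbons"
                )
        dup = rec.duplicated(subset=["metabolite", "mass_shift", "sample"])
        if dup.any():
            raise SchemaError("duplicate (metabolite, mass_shift, sample) records")
        if self.group_of:
            _check_design(sorted(rec["sample"].unique()), self.group_of)
        self.records = rec.reset_index(drop=True)

    @property
    def metabolites(self) -> list[str]:
        return list(dict.fromkeys(self.records["metabolite"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["sample"]))

    def areas(self, metabolite: str, sample: str) -> pd.Series:
        """Areas indexed by mass shift 0..n for one metabolite/sample."""
        sub = self.records[
            (self.records["metabolite"] == metabolite)
            & (self.records["sample"] == sample)
        ]
        n = self.n_carbons[metabolite]
        out = pd.Series(0.0, index=range(n + 1))
        out[sub["mass_shift"].to_numpy()] = sub["area"].to_numpy()
        return out


# ---------------------------------------------------------------------------
# I/O


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) design file."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise SchemaError("design file needs two columns: sample_id, group")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "group"]
    if df["sample_id"].duplicated().any():
        raise DesignError("duplicate sample ids in design file")
    return dict(zip(df["sample_id"], df["group"]))


def _parse_mass_shift(value) -> int:
    s = str(value).strip()
    if s.upper().startswith("M"):
        s = s[1:].lstrip("+")
    return int(s)


def read_table(
    path: str | Path,
    kind: str,
    design: str | Path | Mapping[str, str] | None = None,
    n_carbons: Mapping[str, int] | None = None,
):
    """Read a delimited table of the given ``kind``.

    ``kind`` is one of ``peak``, ``gene``, ``isotopologue``. ``design`` is a
    design-file path or an in-memory sample→group mapping; it is required for
    peak/gene tables. Empty cells and ``NA`` are read as missing, never as 0.
    For peak tables a ``retention_time`` column, when present, is split off
    into the table's metadata. Isotopologue tables need ``n_carbons`` unless
    the file carries an ``n_carbons`` column.
    """
    path = Path(path)
    sep = _sep_for(path)
    group_of: dict[str, str] = {}
    if design is not None:
        group_of = dict(design) if isinstance(design, Mapping) else read_design(design)

    if kind in ("peak", "gene"):
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
        rt = None
        rt_cols = [c for c in df.columns if c.lower().replace(" ", "_") == "retention_time"]
        if rt_cols:
            rt = df[rt_cols[0]].astype(float)
            df = df.drop(columns=rt_cols)
        unknown = [c for c in df.columns if c not in group_of]
        if unknown:
            raise DesignError(f"samples not in design: {unknown}")
        df.index = df.index.astype(str)
        cls = PeakTable if kind == "peak" else GeneTable
        kwargs = {"retention_time": rt} if kind == "peak" else {}
        return cls(values=df, group_of=group_of, **kwargs)

    if kind == "isotopologue":
        rec = pd.read_csv(path, sep=sep, na_values=["NA", ""])
        rename = {c: c.strip().lower() for c in rec.columns}
        rec = rec.rename(columns=rename)
        if "mass_shift" in rec.columns:
            rec["mass_shift"] = [_parse_mass_shift(v) for v in rec["mass_shift"]]
        carbons = dict(n_carbons or {})
        if "n_carbons" in rec.columns:
            for met, sub in rec.groupby("metabolite"):
                carbons.setdefault(str(met), int(sub["n_carbons"].iloc[0]))
            rec = rec.drop(columns=["n_carbons"])
        return IsotopologueTable(records=rec, n_carbons=carbons, group_of=group_of)

    raise ValueError(f"unknown table kind {kind!r}")


def write_results(records, path: str | Path, allow_empty: bool = False) -> Path:
    """Write a result collection to CSV with a single header line.

    Accepts a DataFrame, a sequence of dataclasses, or a sequence of dicts.
    Round-trip stable with :func:`read_results`.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = list(records)
        if rows and dataclasses.is_dataclass(rows[0]):
            rows = [dataclasses.asdict(r) for r in rows]
        df = pd.DataFrame(rows)
    if df.empty and not allow_empty:
        raise ValueError("refusing to write an empty result set (allow_empty=False)")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), na_values=["NA", ""])
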