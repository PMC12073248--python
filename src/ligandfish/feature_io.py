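"""Feature tables, replicate run sets, and compound libraries.

The on-disk format is delimited text (comma or tab).  A feature table needs
the columns ``mz, rt, area, condition, replicate, polarity`` plus optional
``sample, id, height, fragments``; rows that violate the data model are
collected into a rejection report rather than silently dropped.  Retention
times are minutes throughout; fragment lists are semicolon-joined m/z values
in a single column.
"""

from __future__ import annotations

import csv
import importlib.resources
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

from .formula import ElementalComposition, parse_formula, resolve_adduct

__all__ = [
    "Feature",
    "FeatureRun",
    "CompoundRecord",
    "ReadResult",
    "read_feature_table",
    "write_feature_table",
    "filter_min_area",
    "read_compound_library",
    "default_library",
]

#: Default acquisition m/z range (Da); overridable per run.
MZ_RANGE = (40.0, 1200.0)

CONDITIONS = ("control", "enzyme")
POLARITIES = ("negative", "positive")

REQUIRED_COLUMNS = ("mz", "rt", "area", "condition", "replicate", "polarity")


@dataclass(frozen=True)
class Feature:
    """One detected molecular feature: an (m/z, RT, intensity) triple."""

    id: str
    mz: float
    rt: float
    area: float
    height: float = 0.0
    polarity: str = "negative"
    fragments: tuple[float, ...] = ()

    def validate(self, mz_range: tuple[float, float] = MZ_RANGE) -> None:
        if not (mz_range[0] <= self.mz <= mz_range[1]):
            raise ValueError(f"feature {self.id}: m/z {self.mz} outside {mz_range}")
        if self.rt < 0:
            raise ValueError(f"feature {self.id}: negative RT")
        if self.area < 0 or self.height < 0:
            raise ValueError(f"feature {self.id}: negative intensity")
        if self.polarity not in POLARITIES:
            raise ValueError(f"feature {self.id}: polarity {self.polarity!r}")


@dataclass
class FeatureRun:
    """One replicate injection: a set of features with a condition label."""

    sample_id: str
    condition: str
    replicate: int
    polarity: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.replicate < 1:
            raise ValueError("replicate index must be a positive integer")
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate feature ids in run {self.key}")
        for f in self.features:
            if f.polarity != self.polarity:
                raise ValueError(f"feature {f.id} polarity differs from run polarity")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.sample_id, self.condition, self.replicate)


@dataclass(frozen=True)
class CompoundRecord:
    """A compound-library entry used for annotation."""

    name: str
    formula: ElementalComposition
    adducts: tuple[str, ...]
    diagnostic_fragments: tuple[float, ...] = ()
    reference_rt: Optional[float] = None
    #: Published adduct m/z and DBE, when the library carries them.
    reference_mz: Optional[float] = None
    reference_dbe: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.adducts:
            raise ValueError(f"compound {self.name!r} lists no adducts")
        for a in self.adducts:
            resolve_adduct(a)


class ReadResult(NamedTuple):
    runs: list[FeatureRun]
    rejected: pd.DataFrame


def _parse_fragments(cell: object) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    return tuple(float(tok) for tok in text.split(";") if tok.strip())


def read_feature_table(path: "str | Path", delimiter: Optional[str] = None) -> ReadResult:
    """Read a delimited feature table into runs grouped by (sample, condition, replicate).

    Returns a :class:`ReadResult`; malformed rows land in ``rejected`` together
    with the reason, and are never silently dropped.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} is missing required columns: {missing}")
    if "sample" not in df.columns:
        df["sample"] = "sample"
    if "id" not in df.columns:
        df["id"] = [f"f{i}" for i in range(len(df))]
    if "height" not in df.columns:
        df["height"] = 0.0
    if "fragments" not in df.columns:
        df["fragments"] = ""

    runs: dict[tuple[str, str, int], FeatureRun] = {}
    rejects: list[dict] = []
    for row in df.itertuples(index=True):
        try:
            feature = Feature(
                id=str(row.id),
                mz=float(row.mz),
                rt=float(row.rt),
                area=float(row.area),
                height=float(row.height),
                polarity=str(row.polarity).strip().lower(),
                fragments=_parse_fragments(row.fragments),
            )
            feature.validate()
            key = (str(row.sample), str(row.condition).strip().lower(), int(row.replicate))
            if key[1] not in CONDITIONS:
                raise ValueError(f"unknown condition {row.condition!r}")
            run = runs.get(key)
            if run is None:
                run = runs[key] = FeatureRun(key[0], key[1], key[2], feature.polarity, [])
            if feature.polarity != run.polarity:
                raise ValueError("mixed polarity within one run")
            if any(f.id == feature.id for f in run.features):
                raise ValueError(f"duplicate feature id {feature.id!r} in run {key}")
            run.features.append(feature)
        except (ValueError, TypeError) as exc:
            rejects.append({"row": row.Index, "reason": str(exc)})
    rejected = pd.DataFrame(rejects, columns=["row", "reason"])
    return ReadResult(list(runs.values()), rejected)


def write_feature_table(runs: Iterable[FeatureRun], path: "str | Path", delimiter: str = ",") -> None:
    rows = []
    for run in runs:
        for f in run.features:
            rows.append(
                {
                    "sample": run.sample_id,
                    "condition": run.condition,
                    "replicate": run.replicate,
                    "id": f.id,
                    "mz": f.mz,
                    "rt": f.rt,
                    "area": f.area,
                    "height": f.height,
                    "polarity": f.polarity,
                    "fragments": ";".join(repr(float(x)) for x in f.fragments),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False, quoting=csv.QUOTE_MINIMAL)


def filter_min_area(run: FeatureRun, fraction: float = 0.01) -> FeatureRun:
    """Keep features with area >= fraction x max(area); the threshold is inclusive."""
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    if not run.features:
        warnings.warn(f"run {run.key} is empty; nothing to filter", stacklevel=2)
        return run
    threshold = fraction * max(f.area for f in run.features)
    kept = [f for f in run.features if f.area >= threshold]
    return replace(run, features=kept)


def read_compound_library(path: "str | Path") -> list[CompoundRecord]:
    """Read a compound library from delimited text.

    Required columns: ``name, formula, adducts``; optional ``fragments, rt_min``
    plus published reference columns (``reference_mz``, ``reference_dbe``).
    An unparseable formula raises an error naming the compound.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in ("name", "formula", "adducts") if c not in df.columns]
    if missing:
        raise ValueError(f"compound library {path} is missing columns: {missing}")
    records: list[CompoundRecord] = []
    for row in df.itertuples():
        try:
            comp = parse_formula(str(row.formula))
        except Exception as exc:
            raise ValueError(f"compound {row.name!r}: bad formula {row.formula!r}: {exc}") from exc
        adducts = tuple(a.strip() for a in str(row.adducts).split(";") if a.strip())
        records.append(
            CompoundRecord(
                name=str(row.name),
                formula=comp,
                adducts=adducts,
                diagnostic_fragments=_parse_fragments(getattr(row, "fragments", None)),
                reference_rt=_opt_float(getattr(row, "rt_min", None)),
                reference_mz=_opt_float(getattr(row, "reference_mz", None)),
                reference_dbe=_opt_float(getattr(row, "reference_dbe", None)),
            )
        )
    return records


def _opt_float(value: object) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def default_library() -> list[CompoundRecord]:
    """The packaged chamomile-extract compound library (44 entries)."""
    resource = importlib.resources.files("ligandfish") / "data" / "chamomile_library.csv"
    with importlib.resources.as_file(resource) as path:
        return read_compound_library(path)
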