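"""Containers and file I/O for feature tables, cohort designs and trait matrices.

The universal currency of the pipeline is the :class:`FeatureTable`: a
sample-by-feature matrix of non-negative abundances (read counts for taxa,
possibly fractional abundances for inferred pathways), optionally annotated
with per-feature taxonomic lineages.  Tables travel as tab-separated text in
the dominant amplicon convention (features as rows, samples as columns, an
optional trailing ``lineage`` column holding semicolon-delimited ranks), with
a flag to accept the transposed layout.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "CohortDesign",
    "TraitMatrix",
    "read_feature_table",
    "read_design",
    "read_trait_matrix",
    "read_biom_json",
    "write_feature_table",
    "write_design",
    "write_results",
    "parse_lineage",
]

_FLOAT_FMT = "%.12g"  # >= 10 significant digits, bit-stable for round trips


def parse_lineage(text: str) -> tuple[str, ...]:
    """Split a semicolon-delimited lineage string into ordered rank names.

    Whitespace around each rank is stripped and empty slots are preserved as
    empty strings.  Two-letter rank prefixes of the ``g__Veillonella`` dialect
    are removed, so both plain and prefixed annotations map to the same ranks.
    """
    ranks = []
    for rank in str(text).split(";"):
        rank = rank.strip()
        if len(rank) >= 3 and rank[1:3] == "__" and rank[0].isalpha():
            rank = rank[3:]
        ranks.append(rank)
    return tuple(ranks)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class FeatureTable:
    """Sample-by-feature abundance matrix.

    Parameters
    ----------
    data
        DataFrame with samples as the index and features as the columns.
        All entries must be finite and non-negative.
    feature_kind
        ``"taxon"`` or ``"pathway"``.
    lineages
        Optional mapping ``feature_id -> tuple of rank names`` (domain to
        species).  When present, every feature must have a lineage.
    """

    data: pd.DataFrame
    feature_kind: str = "taxon"
    lineages: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if self.feature_kind not in ("taxon", "pathway"):
            raise ValueError(f"feature_kind must be 'taxon' or 'pathway', got {self.feature_kind!r}")
        _check_unique(list(self.data.index), "sample")
        _check_unique(list(self.data.columns), "feature")
        values = self.data.to_numpy()
        if values.size:
            if not np.all(np.isfinite(values)):
                r, c = np.argwhere(~np.isfinite(values))[0]
                raise ValueError(
                    f"non-finite count at sample {self.data.index[r]!r}, feature {self.data.columns[c]!r}"
                )
            if np.any(values < 0):
                r, c = np.argwhere(values < 0)[0]
                raise ValueError(
                    f"negative count at sample {self.data.index[r]!r}, feature {self.data.columns[c]!r}"
                )
        if self.lineages is not None:
            missing = [f for f in self.data.columns if f not in self.lineages]
            if missing:
                raise ValueError(f"features lacking a lineage: {missing[:5]}")
            self.lineages = {f: tuple(self.lineages[f]) for f in self.data.columns}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as a dense ``[sample, feature]`` float array."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str], drop_empty_features: bool = False) -> "FeatureTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        data = self.data.loc[ids]
        if drop_empty_features:
            data = data.loc[:, data.sum(axis=0) > 0]
        lineages = None
        if self.lineages is not None:
            lineages = {f: self.lineages[f] for f in data.columns}
        return FeatureTable(data=data.copy(), feature_kind=self.feature_kind, lineages=lineages)

    def incidence(self) -> pd.DataFrame:
        """Presence/absence matrix (count > 0) as 0/1 integers."""
        return (self.data > 0).astype(np.int8)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.feature_kind == other.feature_kind
            and self.lineages == other.lineages
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.array_equal(self.data.to_numpy(dtype=float), other.data.to_numpy(dtype=float))
        )


@dataclass
class CohortDesign:
    """Assignment of samples to cohorts (metacommunities)."""

    assignments: dict[str, str]
    cohort_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cohort_order:
            seen: list[str] = []
            for c in self.assignments.values():
                if c not in seen:
                    seen.append(c)
            self.cohort_order = seen
        extra = set(self.assignments.values()) - set(self.cohort_order)
        if extra:
            raise ValueError(f"cohorts missing from cohort_order: {sorted(extra)}")

    @property
    def cohorts(self) -> list[str]:
        return list(self.cohort_order)

    def samples_of(self, cohort: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == cohort]

    def require_min_samples(self, n: int) -> None:
        for cohort in self.cohort_order:
            k = len(self.samples_of(cohort))
            if k < n:
                raise ValueError(f"cohort {cohort!r} has {k} samples; at least {n} required")


@dataclass
class TraitMatrix:
    """Feature-by-pathway copy-number matrix used for functional projection."""

    data: pd.DataFrame  # features x pathways

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "feature")
        _check_unique(list(self.data.columns), "pathway")
        values = self.data.to_numpy()
        if values.size and (not np.all(np.isfinite(values)) or np.any(values < 0)):
            raise ValueError("trait copy numbers must be finite and non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.data.columns)


def _coerce_numeric(df: pd.DataFrame, row_kind: str, col_kind: str) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ValueError(
                f"non-numeric value {df.loc[row, col]!r} at {row_kind} {row!r}, {col_kind} {col!r}"
            )
        if converted.isna().any():
            row = df.index[np.flatnonzero(converted.isna().to_numpy())[0]]
            raise ValueError(f"missing value at {row_kind} {row!r}, {col_kind} {col!r}")
        neg = converted < 0
        if neg.any():
            row = df.index[np.flatnonzero(neg.to_numpy())[0]]
            raise ValueError(
                f"negative value {converted[row]!r} at {row_kind} {row!r}, {col_kind} {col!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_feature_table(
    path: str | Path,
    orientation: str = "features_as_rows",
    feature_kind: str = "taxon",
) -> FeatureTable:
    """Read a tab-separated feature table.

    ``features_as_rows`` (the default amplicon convention) expects features as
    rows and samples as columns with an optional final column named
    ``lineage``; ``samples_as_rows`` expects the transpose, with an optional
    final *row* named ``lineage``.  Reading a transposed file with the
    opposite orientation yields an identical table.
    """
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)

    if orientation == "samples_as_rows":
        lineage_row = None
        if "lineage" in raw.index:
            lineage_row = raw.loc["lineage"]
            raw = raw.drop(index="lineage")
        _check_unique(list(raw.index), "sample")
        _check_unique(list(raw.columns), "feature")
        numeric = _coerce_numeric(raw, "sample", "feature")
        lineages = None
        if lineage_row is not None:
            lineages = {f: parse_lineage(lineage_row[f]) for f in numeric.columns}
        return FeatureTable(data=numeric, feature_kind=feature_kind, lineages=lineages)

    lineage_col = None
    if len(raw.columns) and raw.columns[-1] == "lineage":
        lineage_col = raw["lineage"]
        raw = raw.drop(columns="lineage")
    _check_unique(list(raw.index), "feature")
    _check_unique(list(raw.columns), "sample")
    numeric = _coerce_numeric(raw, "feature", "sample")
    lineages = None
    if lineage_col is not None:
        lineages = {f: parse_lineage(lineage_col[f]) for f in numeric.index}
    return FeatureTable(data=numeric.T, feature_kind=feature_kind, lineages=lineages)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table in the features-as-rows TSV dialect (lineage column last)."""
    df = table.data.T.copy()
    if table.lineages is not None:
        df["lineage"] = [";".join(table.lineages[f]) for f in df.index]
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_design(path: str | Path) -> CohortDesign:
    """Read a two-column ``sample_id<TAB>cohort`` metadata file.

    Cohorts are ordered by first appearance.  A sample repeated with the same
    label is deduplicated with a warning; conflicting labels are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"metadata file {path} must have two tab-separated columns")
    sample_col, cohort_col = df.columns[0], df.columns[1]
    assignments: dict[str, str] = {}
    order: list[str] = []
    for sample, cohort in zip(df[sample_col], df[cohort_col]):
        sample, cohort = str(sample), str(cohort)
        if sample in assignments:
            if assignments[sample] != cohort:
                raise ValueError(
                    f"sample {sample!r} listed with conflicting cohorts "
                    f"{assignments[sample]!r} and {cohort!r}"
                )
            warnings.warn(f"sample {sample!r} listed more than once; deduplicated", stacklevel=2)
            continue
        assignments[sample] = cohort
        if cohort not in order:
            order.append(cohort)
    return CohortDesign(assignments=assignments, cohort_order=order)


def write_design(design: CohortDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcohort\n")
        for sample, cohort in design.assignments.items():
            fh.write(f"{sample}\t{cohort}\n")


def read_trait_matrix(path: str | Path) -> TraitMatrix:
    """Read a feature-by-pathway copy-number TSV (features as rows)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    _check_unique(list(raw.index), "feature")
    _check_unique(list(raw.columns), "pathway")
    return TraitMatrix(data=_coerce_numeric(raw, "feature", "pathway"))


def write_trait_matrix(traits: TraitMatrix, path: str | Path) -> None:
    df = traits.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_biom_json(path: str | Path, feature_kind: str = "taxon") -> FeatureTable:
    """Convenience reader for BIOM v1 (JSON) tables.

    Supports dense and sparse matrix types; taxonomy metadata under the
    conventional ``taxonomy`` key becomes the lineage annotation.
    """
    with open(path) as fh:
        doc = json.load(fh)
    sample_ids = [c["id"] for c in doc["columns"]]
    feature_ids = [r["id"] for r in doc["rows"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=float)
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    lineages = None
    if all(r.get("metadata") and "taxonomy" in r["metadata"] for r in doc["rows"]):
        lineages = {
            r["id"]: parse_lineage(";".join(r["metadata"]["taxonomy"]))
            for r in doc["rows"]
        }
    data = pd.DataFrame(mat.T, index=sample_ids, columns=feature_ids)
    return FeatureTable(data=data, feature_kind=feature_kind, lineages=lineages)


def _fmt(x: object) -> object:
    if isinstance(x, (float, np.floating)):
        return float(f"{float(x):.12g}")
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def _jsonable(obj: object) -> object:
    """Recursively convert result records to JSON-serializable structures."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {}
        for f in dataclasses.fields(obj):
            d[f.name] = _jsonable(getattr(obj, f.name))
        # include computed ratio-style properties exposed by result types
        for name in ("nestedness_turnover_ratio",):
            if hasattr(type(obj), name):
                val = getattr(obj, name)
                d[name] = None if (isinstance(val, float) and np.isnan(val)) else _fmt(val)
        return d
    if isinstance(obj, pd.DataFrame):
        return [
            {k: _fmt(v) for k, v in row.items()}
            for row in obj.to_dict(orient="records")
        ]
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _fmt(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def write_results(result: object, path: str | Path, format: str = "json") -> None:
    """Serialize a result record deterministically.

    ``json`` handles any pipeline result.  ``tsv`` is supported for flat
    records: a single multi-site partition becomes a one-row table; a mapping
    of cohort to partition becomes one row per cohort; a list of effect-size
    records becomes one row per feature.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_jsonable(result), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")

    from .beta import BetaPartition  # local import to avoid a cycle

    def partition_row(name: str | None, p: BetaPartition) -> dict:
        row = {
            "beta_sor": p.beta_sor,
            "beta_sim": p.beta_sim,
            "beta_nes": p.beta_nes,
            "n_sites": p.n_sites,
        }
        if name is not None:
            row = {"cohort": name, **row}
        return row

    if isinstance(result, BetaPartition):
        df = pd.DataFrame([partition_row(None, result)])
    elif isinstance(result, Mapping) and all(isinstance(v, BetaPartition) for v in result.values()):
        df = pd.DataFrame([partition_row(k, v) for k, v in result.items()])
    elif isinstance(result, list) and result and dataclasses.is_dataclass(result[0]):
        df = pd.DataFrame([dataclasses.asdict(r) for r in result])
    else:
        raise TypeError(f"cannot serialize {type(result).__name__} as TSV; use json")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
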