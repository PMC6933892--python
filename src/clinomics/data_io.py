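"""Core data model and readers/writers.

The central containers are:

* :class:`OmicMatrix` — a numeric feature × sample matrix for one measurement
  modality ("omic"), with missing values carried as NaN.
* :class:`ClinicalTable` — per-sample clinical labels, each typed as
  categorical, ordinal, numeric, or survival (a time/event pair).
* :class:`Partition` — an assignment of samples or features to clusters 1..k.
* :class:`GeneSetCollection` — named feature sets (GMT-style).
* :class:`DatasetCollection` — several omics over a shared sample universe
  plus one clinical table.

Supported on-disk formats: delimited text matrices, UCSC XENA
genomicMatrix/phenotype TSV pairs, GEO series-matrix files, GMT gene sets,
2-column partition TSVs, and a manifest-JSON + TSV layout for collections.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicMatrix",
    "LabelSpec",
    "ClinicalTable",
    "Partition",
    "GeneSetCollection",
    "DatasetCollection",
    "DEFAULT_MISSING_TOKENS",
    "read_tabular_matrix",
    "read_xena_pair",
    "read_geo_series_matrix",
    "read_partition",
    "read_gene_sets",
    "write_collection",
    "read_collection",
]

#: Missing-value tokens recognized by all text readers (case-insensitive).
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "null")

LabelKind = Literal["categorical", "ordinal", "numeric", "survival"]
Axis = Literal["samples", "features"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = 1
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))[:10]}")


@dataclass
class OmicMatrix:
    """A feature × sample numeric matrix for one omic.

    ``values`` is a float array of shape (n_features, n_samples); missing
    entries are NaN and also exposed through :attr:`mask`.
    """

    omic_name: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_scale: str = ""

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask, True where the value is missing."""
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, omic_name: str = "", value_scale: str = "") -> "OmicMatrix":
        return cls(
            omic_name=omic_name,
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            value_scale=value_scale,
        )

    def copy(self) -> "OmicMatrix":
        return OmicMatrix(
            self.omic_name, list(self.feature_ids), list(self.sample_ids),
            self.values.copy(), self.value_scale,
        )

    def feature_index(self, feature: str) -> int:
        try:
            return self.feature_ids.index(feature)
        except ValueError:
            raise KeyError(f"feature {feature!r} not in matrix") from None

    def subset(self, features: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "OmicMatrix":
        """Restrict to the given features/samples, in the order given."""
        fi = list(range(self.n_features)) if features is None else [
            self.feature_index(f) for f in features]
        smap = {s: j for j, s in enumerate(self.sample_ids)}
        if samples is None:
            si = list(range(self.n_samples))
        else:
            missing = [s for s in samples if s not in smap]
            if missing:
                raise KeyError(f"samples not in matrix: {missing[:10]}")
            si = [smap[s] for s in samples]
        return OmicMatrix(
            self.omic_name,
            [self.feature_ids[i] for i in fi],
            [self.sample_ids[j] for j in si],
            self.values[np.ix_(fi, si)].copy(),
            self.value_scale,
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class LabelSpec:
    """Declared type of one clinical label.

    For ordinal labels ``levels`` gives the low-to-high level ordering.
    """

    name: str
    kind: LabelKind
    levels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "ordinal", "numeric", "survival"):
            raise ValueError(f"unknown label type {self.kind!r} for {self.name!r}")
        if self.kind == "ordinal" and not self.levels:
            raise ValueError(f"ordinal label {self.name!r} requires explicit levels")


class ClinicalTable:
    """Per-sample clinical labels of mixed types.

    Non-survival labels are pandas Series indexed by sample id; survival
    labels are two-column (time, event) DataFrames. Missing entries are NaN.
    """

    def __init__(self, sample_ids: Sequence[str],
                 columns: Mapping[str, pd.Series | pd.DataFrame] | None = None,
                 specs: Mapping[str, LabelSpec] | None = None):
        self.sample_ids = [str(s) for s in sample_ids]
        _check_unique(self.sample_ids, "sample")
        self._columns: dict[str, pd.Series | pd.DataFrame] = {}
        self.specs: dict[str, LabelSpec] = {}
        if columns:
            for name, col in columns.items():
                spec = (specs or {}).get(name)
                if spec is None:
                    raise ValueError(f"no LabelSpec for column {name!r}")
                self.add_label(name, col, spec)

    # -- construction ----------------------------------------------------
    def add_label(self, name: str, values: pd.Series | pd.DataFrame,
                  spec: LabelSpec) -> None:
        if name in self._columns:
            raise ValueError(f"label {name!r} already present")
        idx = pd.Index(self.sample_ids)
        if spec.kind == "survival":
            if not isinstance(values, pd.DataFrame) or list(values.columns) != ["time", "event"]:
                raise ValueError("survival label needs a DataFrame with columns ['time','event']")
            values = values.reindex(idx)
            t = values["time"].to_numpy(dtype=float)
            e = values["event"].to_numpy(dtype=float)
            ok = ~np.isnan(t)
            if np.any(t[ok] < 0):
                raise ValueError(f"survival label {name!r} has negative times")
            eobs = e[~np.isnan(e)]
            if not np.all(np.isin(eobs, (0.0, 1.0))):
                raise ValueError(f"survival label {name!r} has non-binary event flags")
        else:
            values = pd.Series(values).reindex(idx)
            if spec.kind == "numeric":
                values = pd.to_numeric(values, errors="raise").astype(float)
            elif spec.kind == "ordinal":
                obs = set(values.dropna().astype(str))
                extra = obs - set(spec.levels or [])
                if extra:
                    raise ValueError(
                        f"ordinal label {name!r} has values outside declared levels: {sorted(extra)}")
        self._columns[name] = values
        self.specs[name] = spec

    # -- accessors -------------------------------------------------------
    @property
    def label_names(self) -> list[str]:
        return list(self._columns)

    def kind(self, name: str) -> LabelKind:
        return self._spec(name).kind

    def _spec(self, name: str) -> LabelSpec:
        if name not in self.specs:
            raise KeyError(f"unknown clinical label {name!r}")
        return self.specs[name]

    def get(self, name: str) -> pd.Series:
        """Values of a non-survival label, indexed by sample id."""
        if self._spec(name).kind == "survival":
            raise TypeError(f"label {name!r} is a survival label; use get_survival")
        return self._columns[name]

    def get_survival(self, name: str) -> tuple[pd.Series, pd.Series]:
        """(time, event) of a survival label, indexed by sample id."""
        if self._spec(name).kind != "survival":
            raise TypeError(f"label {name!r} is not a survival label")
        df = self._columns[name]
        return df["time"], df["event"]

    def ordinal_ranks(self, name: str) -> pd.Series:
        """Ordinal label mapped to 0..len(levels)-1 numeric ranks."""
        spec = self._spec(name)
        if spec.kind != "ordinal":
            raise TypeError(f"label {name!r} is not ordinal")
        lut = {lvl: float(i) for i, lvl in enumerate(spec.levels or [])}
        return self._columns[name].map(lambda v: lut.get(str(v), np.nan) if pd.notna(v) else np.nan)

    def subset(self, samples: Sequence[str]) -> "ClinicalTable":
        sub = ClinicalTable(samples)
        idx = pd.Index([str(s) for s in samples])
        for name, spec in self.specs.items():
            col = self._columns[name].reindex(idx)
            sub._columns[name] = col
            sub.specs[name] = spec
        return sub

    def to_frame(self) -> pd.DataFrame:
        """Flat view: survival labels expand to <name>_time / <name>_event."""
        cols = {}
        for name, spec in self.specs.items():
            if spec.kind == "survival":
                df = self._columns[name]
                cols[f"{name}_time"] = df["time"]
                cols[f"{name}_event"] = df["event"]
            else:
                cols[name] = self._columns[name]
        return pd.DataFrame(cols, index=pd.Index(self.sample_ids, name="sample"))


@dataclass
class Partition:
    """Assignment of samples or features to clusters 1..k."""

    axis: Axis
    assignments: dict[str, int]
    k: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.axis not in ("samples", "features"):
            raise ValueError(f"axis must be 'samples' or 'features', got {self.axis!r}")
        got = set(self.assignments.values())
        if got != set(range(1, self.k + 1)):
            raise ValueError(
                f"clusters must be exactly 1..{self.k} and all non-empty; got {sorted(got)}")

    @classmethod
    def from_labels(cls, axis: Axis, ids: Sequence[str], labels: Sequence[int],
                    provenance: str = "") -> "Partition":
        """Build from 0- or 1-based integer labels, renumbering to 1..k by first appearance."""
        mapping: dict[int, int] = {}
        assignments: dict[str, int] = {}
        for i, lab in zip(ids, labels):
            lab = int(lab)
            if lab not in mapping:
                mapping[lab] = len(mapping) + 1
            assignments[str(i)] = mapping[lab]
        return cls(axis=axis, assignments=assignments, k=len(mapping), provenance=provenance)

    @property
    def ids(self) -> list[str]:
        return list(self.assignments)

    def labels_for(self, ids: Sequence[str]) -> np.ndarray:
        missing = [i for i in ids if str(i) not in self.assignments]
        if missing:
            raise KeyError(f"ids not covered by partition: {missing[:10]}")
        return np.array([self.assignments[str(i)] for i in ids], dtype=int)

    def members(self, cluster: int) -> list[str]:
        if not 1 <= cluster <= self.k:
            raise KeyError(f"cluster {cluster} not in 1..{self.k}")
        return [i for i, c in self.assignments.items() if c == cluster]

    def sizes(self) -> dict[int, int]:
        out = {c: 0 for c in range(1, self.k + 1)}
        for c in self.assignments.values():
            out[c] += 1
        return out

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tcluster\n")
            for i, c in self.assignments.items():
                fh.write(f"{i}\t{c}\n")


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, member ids)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, (desc, members) in self.sets.items():
                fh.write("\t".join([name, desc, *members]) + "\n")


@dataclass
class DatasetCollection:
    """Named omics over a shared sample universe, plus one clinical table."""

    omics: dict[str, OmicMatrix]
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        _check_unique(list(self.omics), "omic name")
        clin = set(self.clinical.sample_ids)
        for name, om in self.omics.items():
            extra = set(om.sample_ids) - clin
            if extra:
                raise ValueError(
                    f"omic {name!r} has samples absent from the clinical table: {sorted(extra)[:10]}")

    @property
    def sample_universe(self) -> list[str]:
        """Samples present in at least one omic, in clinical-table order."""
        seen = set()
        for om in self.omics.values():
            seen.update(om.sample_ids)
        return [s for s in self.clinical.sample_ids if s in seen]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _normalize_missing(tokens: Iterable[str]) -> set[str]:
    return {t.lower() for t in tokens}


def _parse_cell(tok: str, missing: set[str], path: str, line_no: int) -> float:
    if tok.strip().lower() in missing:
        return np.nan
    try:
        return float(tok)
    except ValueError:
        raise ValueError(
            f"{path}:{line_no}: non-numeric cell {tok!r} not in missing tokens") from None


def read_tabular_matrix(path: str | Path, delimiter: str = "\t",
                        orientation: Literal["features_in_rows", "samples_in_rows"] = "features_in_rows",
                        missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
                        omic_name: str | None = None,
                        value_scale: str = "") -> OmicMatrix:
    """Read a delimited text matrix with row/column ids into an OmicMatrix.

    The first row holds column ids (first cell is a corner label and is
    ignored), each following row starts with a row id. ``orientation``
    declares whether file rows are features or samples; the result is always
    features × samples.
    """
    path = Path(path)
    missing = _normalize_missing(missing_tokens)
    with open(path) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header plus at least one data row")
    header = lines[0].split(delimiter)
    col_ids = [c.strip() for c in header[1:]]
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for ln_no, ln in enumerate(lines[1:], start=2):
        parts = ln.split(delimiter)
        if len(parts) != len(col_ids) + 1:
            raise ValueError(
                f"{path}:{ln_no}: ragged row with {len(parts)} fields, expected {len(col_ids) + 1}")
        row_ids.append(parts[0].strip())
        rows.append([_parse_cell(t, missing, str(path), ln_no) for t in parts[1:]])
    values = np.asarray(rows, dtype=float)
    if orientation == "samples_in_rows":
        values = values.T
        feature_ids, sample_ids = col_ids, row_ids
    else:
        feature_ids, sample_ids = row_ids, col_ids
    return OmicMatrix(
        omic_name=omic_name if omic_name is not None else path.stem,
        feature_ids=feature_ids, sample_ids=sample_ids,
        values=values, value_scale=value_scale,
    )


def _looks_numeric(vals: pd.Series) -> bool:
    converted = pd.to_numeric(vals, errors="coerce")
    return bool(converted.notna().all())


def autotype_labels(df: pd.DataFrame,
                    label_types: Mapping[str, str | LabelSpec] | None = None,
                    survival_pairs: Mapping[str, tuple[str, str]] | None = None,
                    max_categories: int = 10) -> ClinicalTable:
    """Build a typed ClinicalTable from a raw per-sample label frame.

    Explicit declarations in ``label_types`` win; undeclared columns are
    auto-typed: all-numeric non-binary -> numeric; <= ``max_categories``
    distinct tokens -> categorical; column pairs named ``<base>_time`` /
    ``<base>_event`` (with binary 0/1 events) are assembled into a survival
    label ``<base>``. Ordinal typing is never inferred. Columns that fit no
    rule are kept as categorical with a warning if high-cardinality.
    """
    df = df.copy()
    df.index = df.index.astype(str)
    table = ClinicalTable(list(df.index))
    declared: dict[str, LabelSpec] = {}
    for name, spec in (label_types or {}).items():
        declared[name] = spec if isinstance(spec, LabelSpec) else LabelSpec(name, spec)  # type: ignore[arg-type]

    consumed: set[str] = set()
    pairs = dict(survival_pairs or {})
    # suffix-pair survival auto-detection
    for col in df.columns:
        if col.endswith("_time"):
            base = col[: -len("_time")]
            ev = f"{base}_event"
            if ev in df.columns and base not in pairs and base not in declared:
                pairs[base] = (col, ev)
    for base, (tcol, ecol) in pairs.items():
        if tcol not in df.columns or ecol not in df.columns:
            raise KeyError(f"survival pair columns {tcol!r}/{ecol!r} not found")
        sub = pd.DataFrame({
            "time": pd.to_numeric(df[tcol], errors="coerce"),
            "event": pd.to_numeric(df[ecol], errors="coerce"),
        }, index=df.index)
        table.add_label(base, sub, LabelSpec(base, "survival"))
        consumed.update((tcol, ecol))

    for col in df.columns:
        if col in consumed:
            continue
        vals = df[col]
        obs = vals.dropna().astype(str)
        obs = obs[~obs.str.strip().str.lower().isin(_normalize_missing(DEFAULT_MISSING_TOKENS))]
        vals = vals.where(vals.index.isin(obs.index), np.nan)
        if col in declared:
            spec = declared[col]
            if spec.kind == "survival":
                raise ValueError(
                    f"survival label {col!r} must be declared via a (time,event) column pair")
            table.add_label(col, vals, spec)
            continue
        if len(obs) == 0:
            table.add_label(col, vals, LabelSpec(col, "categorical"))
            continue
        is_01_flag = _looks_numeric(obs) and set(
            pd.to_numeric(obs).unique().tolist()) <= {0.0, 1.0}
        if _looks_numeric(obs) and not is_01_flag:
            table.add_label(col, pd.to_numeric(vals, errors="coerce"), LabelSpec(col, "numeric"))
        else:
            if obs.nunique() > max_categories:
                warnings.warn(
                    f"label {col!r} has {obs.nunique()} distinct values; keeping as categorical")
            table.add_label(col, vals.astype(object), LabelSpec(col, "categorical"))
    return table


def read_xena_pair(matrix_path: str | Path, phenotype_path: str | Path,
                   label_types: Mapping[str, str | LabelSpec] | None = None,
                   survival_pairs: Mapping[str, tuple[str, str]] | None = None,
                   omic_name: str | None = None) -> tuple[OmicMatrix, ClinicalTable]:
    """Read a UCSC XENA genomicMatrix TSV plus its clinical phenotype TSV.

    The matrix has identifiers in the first column and samples in the header;
    the phenotype file has samples in rows and labels in columns. Sample ids
    are intersected (matrix order kept); ``survival_pairs`` maps a label name
    to its (time column, event column) pair, e.g. ``{"OS": ("OS.time", "OS")}``.
    """
    matrix = read_tabular_matrix(matrix_path, omic_name=omic_name)
    pheno = pd.read_csv(phenotype_path, sep="\t", index_col=0, dtype=object)
    pheno.index = pheno.index.astype(str)
    shared = [s for s in matrix.sample_ids if s in set(pheno.index)]
    if not shared:
        raise ValueError("no samples shared between matrix and phenotype file")
    dropped = len(matrix.sample_ids) - len(shared)
    if dropped or len(pheno) != len(shared):
        warnings.warn(
            f"sample intersection: kept {len(shared)}, dropped {dropped} matrix-only "
            f"and {len(pheno) - len(shared)} phenotype-only samples")
    matrix = matrix.subset(samples=shared)
    clinical = autotype_labels(pheno.loc[shared], label_types=label_types,
                               survival_pairs=survival_pairs)
    return matrix, clinical


def read_geo_series_matrix(path: str | Path) -> tuple[OmicMatrix, ClinicalTable]:
    """Parse a GEO series-matrix text file.

    The expression table is taken between the ``!series_matrix_table_begin`` /
    ``!series_matrix_table_end`` markers. Each ``!Sample_characteristics_ch1``
    line whose entries look like ``key: value`` becomes a clinical label named
    ``key``; labels are auto-typed. Only the series-matrix dialect is
    supported (not full SOFT).
    """
    path = Path(path)
    sample_ids: list[str] | None = None
    char_rows: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            low = line.lower()
            if low.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if low.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
                continue
            if line.startswith("!Sample_geo_accession"):
                sample_ids = [t.strip().strip('"') for t in line.split("\t")[1:]]
            elif line.startswith("!Sample_characteristics_ch1"):
                char_rows.append([t.strip().strip('"') for t in line.split("\t")[1:]])
    if not (saw_begin and saw_end):
        raise ValueError(f"{path}: series-matrix table markers not found")
    if not table_lines:
        raise ValueError(f"{path}: empty series-matrix table")

    header = [t.strip().strip('"') for t in table_lines[0].split("\t")]
    col_ids = header[1:]
    feat_ids, rows = [], []
    missing = _normalize_missing(DEFAULT_MISSING_TOKENS)
    for ln_no, ln in enumerate(table_lines[1:], start=2):
        parts = [t.strip().strip('"') for t in ln.split("\t")]
        if len(parts) != len(col_ids) + 1:
            raise ValueError(f"{path}: ragged table row {ln_no}")
        feat_ids.append(parts[0])
        rows.append([_parse_cell(t, missing, str(path), ln_no) for t in parts[1:]])
    matrix = OmicMatrix(omic_name=path.stem, feature_ids=feat_ids,
                        sample_ids=col_ids, values=np.asarray(rows, dtype=float))
    if sample_ids is None:
        sample_ids = col_ids

    # characteristics lines -> key: value labels
    label_data: dict[str, dict[str, object]] = {}
    for row in char_rows:
        keys_here = []
        for sid, entry in zip(sample_ids, row):
            if not entry or ":" not in entry:
                continue
            key, val = entry.split(":", 1)
            key, val = key.strip(), val.strip()
            keys_here.append(key)
            label_data.setdefault(key, {})[sid] = val
        if keys_here and len(set(keys_here)) > 1:
            warnings.warn(
                f"{path}: inconsistent characteristics keys {sorted(set(keys_here))} "
                "within one line; entries kept under their own keys")
    frame = pd.DataFrame(index=pd.Index(matrix.sample_ids, dtype=str))
    for key, vals in label_data.items():
        frame[key] = pd.Series(vals).reindex(frame.index)
    clinical = autotype_labels(frame)
    return matrix, clinical


def read_partition(path: str | Path, axis: Axis = "samples") -> Partition:
    """Read a 2-column (id, group) TSV; groups are numbered 1..k in first-appearance order."""
    path = Path(path)
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for ln_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln_no}: expected 2 tab-separated fields")
            ident, group = parts[0].strip(), parts[1].strip()
            if ln_no == 1 and ident.lower() in ("id", "sample", "feature") and group.lower() in ("cluster", "group"):
                continue  # optional header
            if ident in assignments:
                if assignments[ident] != group:
                    raise ValueError(f"{path}:{ln_no}: id {ident!r} assigned to conflicting groups")
                raise ValueError(f"{path}:{ln_no}: duplicate id {ident!r}")
            assignments[ident] = group
    if not assignments:
        raise ValueError(f"{path}: empty partition file")
    order: dict[str, int] = {}
    out: dict[str, int] = {}
    for ident, group in assignments.items():
        if group not in order:
            order[group] = len(order) + 1
        out[ident] = order[group]
    return Partition(axis=axis, assignments=out, k=len(order),
                     provenance=f"file:{path.name}")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member..."""
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for ln_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln_no}: GMT line needs >= 3 fields")
            name, desc = parts[0], parts[1]
            if name in sets:
                raise ValueError(f"{path}:{ln_no}: duplicate gene-set name {name!r}")
            members = list(dict.fromkeys(m for m in parts[2:] if m.strip()))
            if not members:
                raise ValueError(f"{path}:{ln_no}: gene set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# Collection layout: manifest JSON + TSVs
# ---------------------------------------------------------------------------

_MANIFEST = "manifest.json"


def write_collection(collection: DatasetCollection, directory: str | Path) -> None:
    """Write a collection as manifest.json + one TSV per omic + clinical TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format": "clinomics-collection", "version": 1,
                      "omics": [], "clinical": {"file": "clinical.tsv", "labels": []}}
    for name, om in collection.omics.items():
        fname = f"omic_{name}.tsv"
        om.write_tsv(directory / fname)
        manifest["omics"].append({"name": name, "file": fname, "value_scale": om.value_scale})
    clin = collection.clinical
    flat = clin.to_frame()
    flat.to_csv(directory / "clinical.tsv", sep="\t", na_rep="NA")
    for name, spec in clin.specs.items():
        entry: dict = {"name": name, "type": spec.kind}
        if spec.kind == "ordinal":
            entry["levels"] = spec.levels
        if spec.kind == "survival":
            entry["columns"] = [f"{name}_time", f"{name}_event"]
        manifest["clinical"]["labels"].append(entry)
    with open(directory / _MANIFEST, "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_collection(directory: str | Path) -> DatasetCollection:
    """Read a collection written by :func:`write_collection`."""
    directory = Path(directory)
    with open(directory / _MANIFEST) as fh:
        manifest = json.load(fh)
    omics: dict[str, OmicMatrix] = {}
    for entry in manifest["omics"]:
        fpath = directory / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing file {entry['file']!r}")
        omics[entry["name"]] = read_tabular_matrix(
            fpath, omic_name=entry["name"], value_scale=entry.get("value_scale", ""))
    cpath = directory / manifest["clinical"]["file"]
    if not cpath.exists():
        raise FileNotFoundError(f"manifest references missing clinical file {cpath.name!r}")
    flat = pd.read_csv(cpath, sep="\t", index_col=0, dtype=object)
    flat.index = flat.index.astype(str)
    table = ClinicalTable(list(flat.index))
    for entry in manifest["clinical"]["labels"]:
        name, kind = entry["name"], entry["type"]
        if kind not in ("categorical", "ordinal", "numeric", "survival"):
            raise ValueError(f"manifest declares unknown label type {kind!r} for {name!r}")
        if kind == "survival":
            tcol, ecol = entry["columns"]
            sub = pd.DataFrame({"time": pd.to_numeric(flat[tcol], errors="coerce"),
                                "event": pd.to_numeric(flat[ecol], errors="coerce")},
                               index=flat.index)
            table.add_label(name, sub, LabelSpec(name, "survival"))
        elif kind == "numeric":
            table.add_label(name, pd.to_numeric(flat[name], errors="coerce"),
                            LabelSpec(name, "numeric"))
        else:
            vals = flat[name].where(flat[name].notna() & (flat[name].astype(str) != "NA"), np.nan)
            table.add_label(name, vals, LabelSpec(name, kind, entry.get("levels")))
    return DatasetCollection(omics=omics, clinical=table)
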