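"""Data model and I/O for analyte tables, sample metadata and network graphs.

Four assays are handled throughout the package: immune-cell population
frequencies measured in blood and in colonic biopsies (CyTOF-style percent
of parent population), and ASV count tables from fecal and colonic-biopsy
16S sequencing.  An :class:`AnalyteTable` is a dense samples x analytes
matrix tagged with its assay and the kind of value it holds; sample-level
covariates (cohort, age, collection day, gender, per-assay read depths,
behavior-questionnaire answers) live in a :class:`SampleMetadata`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

ASSAYS = ("blood_cells", "colonic_cells", "fecal_microbes", "colonic_microbes")
MICROBE_ASSAYS = frozenset({"fecal_microbes", "colonic_microbes"})
IMMUNE_ASSAYS = frozenset({"blood_cells", "colonic_cells"})

VALUE_KINDS = ("percent_frequency", "counts", "pph", "arcsinh_pph")

#: Cohort labels in canonical order (reference cohort first).
COHORTS = ("HIV- non-MSM", "HIV- MSM", "HIV+ MSM")

#: (HIV status, MSM status) is a pure function of cohort.
COHORT_STATUS = {
    "HIV- non-MSM": (0, 0),
    "HIV- MSM": (0, 1),
    "HIV+ MSM": (1, 1),
}


class TableError(ValueError):
    """Malformed table or metadata input."""


def _reads_column(assay: str) -> str:
    return f"reads_{assay}"


def _behavior_column(key: str) -> str:
    return f"behavior_{key}"


@dataclass(frozen=True)
class AnalyteTable:
    """Samples x analytes matrix for one assay.

    ``values`` is a float (or integer, for counts) matrix whose rows follow
    ``sample_ids`` and columns follow ``analyte_ids``.
    """

    sample_ids: tuple
    analyte_ids: tuple
    values: np.ndarray
    assay: str
    value_kind: str

    def __post_init__(self):
        if self.assay not in ASSAYS:
            raise TableError(f"unknown assay {self.assay!r}")
        if self.value_kind not in VALUE_KINDS:
            raise TableError(f"unknown value_kind {self.value_kind!r}")
        vals = np.asarray(self.values)
        if vals.shape != (len(self.sample_ids), len(self.analyte_ids)):
            raise TableError(
                f"values shape {vals.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.analyte_ids)} analytes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableError("duplicate sample ids")
        if len(set(self.analyte_ids)) != len(self.analyte_ids):
            raise TableError("duplicate analyte ids (disambiguate first)")
        if self.value_kind == "counts":
            if np.any(vals < 0):
                raise TableError("counts must be non-negative")
            if not np.allclose(vals, np.round(vals)):
                raise TableError("counts must be integers")
        elif self.value_kind == "percent_frequency":
            if np.any(vals < -1e-9) or np.any(vals > 100 + 1e-9):
                raise TableError("percent frequencies must lie in [0, 100]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_analytes(self) -> int:
        return len(self.analyte_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.values),
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=list(self.analyte_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, assay: str, value_kind: str) -> "AnalyteTable":
        return cls(
            sample_ids=tuple(str(s) for s in frame.index),
            analyte_ids=tuple(str(a) for a in frame.columns),
            values=frame.to_numpy(dtype=float),
            assay=assay,
            value_kind=value_kind,
        )

    def column(self, analyte_id: str) -> np.ndarray:
        j = self.analyte_ids.index(analyte_id)
        return np.asarray(self.values)[:, j]

    def subset_samples(self, sample_ids) -> "AnalyteTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise TableError(f"sample {exc.args[0]!r} not in table") from exc
        return replace(
            self,
            sample_ids=tuple(sample_ids),
            values=np.asarray(self.values)[rows, :],
        )

    def subset_analytes(self, analyte_ids) -> "AnalyteTable":
        index = {a: j for j, a in enumerate(self.analyte_ids)}
        cols = [index[a] for a in analyte_ids]
        return replace(
            self,
            analyte_ids=tuple(analyte_ids),
            values=np.asarray(self.values)[:, cols],
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample covariates, keyed by sample id.

    The underlying frame has columns ``cohort``, ``hiv_status``,
    ``msm_status``, ``gender``, ``age``, ``day``, one ``reads_<assay>``
    column per microbe assay, and ``behavior_<key>`` columns for
    questionnaire answers (missing answers are NA).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        if f.index.has_duplicates:
            raise TableError("duplicate sample ids in metadata")
        required = {"cohort", "gender", "age", "day"}
        missing = required - set(f.columns)
        if missing:
            raise TableError(f"metadata missing columns: {sorted(missing)}")
        bad = set(f["cohort"].unique()) - set(COHORTS)
        if bad:
            raise TableError(f"unknown cohort labels: {sorted(bad)}")
        # hiv/msm are a pure function of cohort; derive if absent, check if present
        derived = f["cohort"].map(lambda c: COHORT_STATUS[c])
        hiv = derived.map(lambda t: t[0]).astype(int)
        msm = derived.map(lambda t: t[1]).astype(int)
        if "hiv_status" in f.columns:
            if not (f["hiv_status"].astype(int) == hiv).all():
                raise TableError("hiv_status inconsistent with cohort")
        else:
            f = f.assign(hiv_status=hiv)
        if "msm_status" in f.columns:
            if not (f["msm_status"].astype(int) == msm).all():
                raise TableError("msm_status inconsistent with cohort")
        else:
            f = f.assign(msm_status=msm)
        for col in f.columns:
            if col.startswith("reads_") and (f[col].dropna() < 0).any():
                raise TableError(f"negative read counts in {col}")
        object.__setattr__(self, "frame", f)

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.frame.index)

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    def cohort_counts(self) -> dict:
        vc = self.frame["cohort"].value_counts()
        return {c: int(vc.get(c, 0)) for c in COHORTS}

    def reads(self, assay: str) -> pd.Series:
        col = _reads_column(assay)
        if col not in self.frame.columns:
            raise TableError(f"metadata has no read counts for assay {assay!r}")
        return self.frame[col]

    def has_reads(self, assay: str) -> bool:
        return _reads_column(assay) in self.frame.columns

    @property
    def behavior_questions(self) -> tuple:
        return tuple(
            c[len("behavior_"):] for c in self.frame.columns if c.startswith("behavior_")
        )

    def behavior(self, key: str) -> pd.Series:
        return self.frame[_behavior_column(key)]

    def subset(self, sample_ids) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise TableError(f"samples absent from metadata: {missing[:5]}")
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# readers / writers


def disambiguate_analyte_ids(ids) -> list:
    """Make analyte names unique by appending a trailing sequence number.

    The second occurrence of a name becomes ``name.2``, the third ``name.3``
    and so on; first occurrences are left untouched.
    """
    seen: dict = {}
    out = []
    for name in ids:
        name = str(name)
        if name not in seen:
            seen[name] = 1
            out.append(name)
        else:
            seen[name] += 1
            candidate = f"{name}.{seen[name]}"
            while candidate in seen:
                seen[name] += 1
                candidate = f"{name}.{seen[name]}"
            seen[candidate] = 1
            out.append(candidate)
    return out


def read_analyte_table(path, assay: str, value_kind: str) -> AnalyteTable:
    """Read a TSV with a header row of analyte ids and first column of sample ids."""
    # read the header line verbatim: pandas would rename duplicate analyte
    # names itself, bypassing the trailing-number convention below
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    frame = pd.read_csv(path, sep="\t", index_col=0, header=None, skiprows=1)
    frame.index = frame.index.astype(str)
    if frame.shape[1] != len(header) - 1:
        raise TableError(f"{path}: header/data column count mismatch")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise TableError(f"{path}: duplicate sample ids {dupes[:5]}")
    frame.columns = disambiguate_analyte_ids(header[1:])
    arr = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            arr[:, j] = pd.to_numeric(frame[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise TableError(f"{path}: non-numeric value in column {col!r}") from exc
    if value_kind == "counts":
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise TableError(
                f"{path}: negative count at sample {frame.index[i]!r}, "
                f"analyte {frame.columns[j]!r}"
            )
    return AnalyteTable(
        sample_ids=tuple(str(s) for s in frame.index),
        analyte_ids=tuple(frame.columns),
        values=arr,
        assay=assay,
        value_kind=value_kind,
    )


def write_analyte_table(table: AnalyteTable, path) -> None:
    frame = table.to_frame()
    if table.value_kind == "counts":
        frame = frame.astype(int)
    frame.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.index.name = "sample_id"
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t")


@dataclass
class AlignmentReport:
    """Which samples each input lost when restricting to the common set."""

    shared: tuple
    dropped: dict = field(default_factory=dict)

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def align_samples(tables, metadata: SampleMetadata):
    """Restrict tables and metadata to samples present in all inputs.

    Samples are put in a canonical lexicographic order.  Returns
    ``(aligned_tables, aligned_metadata, report)``.
    """
    if not tables:
        raise TableError("no tables to align")
    shared = set(metadata.sample_ids)
    for t in tables:
        shared &= set(t.sample_ids)
    if not shared:
        raise TableError("no samples shared by all inputs")
    order = tuple(sorted(shared))
    dropped = {
        f"table_{i}_{t.assay}": sorted(set(t.sample_ids) - shared)
        for i, t in enumerate(tables)
    }
    dropped["metadata"] = sorted(set(metadata.sample_ids) - shared)
    aligned = [t.subset_samples(order) for t in tables]
    return aligned, metadata.subset(order), AlignmentReport(shared=order, dropped=dropped)


# ---------------------------------------------------------------------------
# network export


def network_to_graphml(graph: nx.Graph, path) -> None:
    """Write a network with scalar node/edge attributes as GraphML."""
    clean = nx.Graph()
    for node, attrs in graph.nodes(data=True):
        clean.add_node(node, **{k: _graphml_scalar(v) for k, v in attrs.items()})
    for u, v, attrs in graph.edges(data=True):
        clean.add_edge(u, v, **{k: _graphml_scalar(val) for k, val in attrs.items()})
    nx.write_graphml(clean, path)


def _graphml_scalar(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (str, int, float, bool)):
        return value
    return str(value)


def network_to_edge_table(graph: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, attrs in graph.edges(data=True):
        row = {"analyte_a": u, "analyte_b": v}
        row.update({k: _graphml_scalar(val) for k, val in attrs.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_network(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Export a network as GraphML or a flat tab-separated edge table."""
    if format == "graphml":
        network_to_graphml(graph, path)
    elif format == "edge_tsv":
        network_to_edge_table(graph).to_csv(path, sep="\t", index=False)
    else:
        raise TableError(f"unknown network format {format!r}")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
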