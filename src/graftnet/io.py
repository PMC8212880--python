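"""Readers and writers for the pipeline's external formats.

Canonical dialects:

* abundance tables — TSV, header row of sample ids, first column protein ids,
  empty cells or ``NA`` mark missing values (distinct from observed zeros);
* sample annotations — TSV with columns ``sample_id``, ``condition``,
  ``timepoint``, ``replicate``;
* gene sets — standard GMT (``set_id<TAB>description<TAB>member...``);
* interactomes — 2-column edge lists or 3-column SIF (interaction token ignored);
* result tables — TSV with a deterministic, sorted row order.

Protein/gene identifiers are case-normalized to uppercase at every boundary
(mouse and human symbol conventions differ only in case).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError, FormatError

ANNOTATION_COLUMNS = ("sample_id", "condition", "timepoint", "replicate")
MISSING_TOKENS = ("", "NA")


@dataclass(frozen=True)
class SampleAnnotation:
    """Condition / timepoint / replicate labels for one sample column."""

    sample_id: str
    condition: str
    timepoint: str
    replicate: int


class AbundanceTable:
    """Proteins × samples non-negative abundance matrix with sample annotations.

    ``data`` is a float DataFrame indexed by unique uppercase protein ids with
    one column per sample; missing measurements are NaN.  ``annotations`` is a
    DataFrame with :data:`ANNOTATION_COLUMNS`, row-aligned to the columns of
    ``data``.
    """

    def __init__(self, data: pd.DataFrame, annotations: pd.DataFrame):
        data = data.copy()
        data.index = data.index.astype(str).str.upper()
        data.index.name = "protein_id"
        data.columns = data.columns.astype(str)
        if data.index.duplicated().any():
            dups = sorted(data.index[data.index.duplicated()].unique())
            raise FormatError(f"duplicate protein ids: {dups}")
        values = data.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise FormatError("abundance values must be finite or missing")
        if np.nanmin(values, initial=0.0) < 0:
            raise FormatError("abundance values must be non-negative")
        data = data.astype(float)

        annotations = annotations.copy()
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
        if missing_cols:
            raise FormatError(f"annotation table lacks columns: {missing_cols}")
        annotations = annotations.loc[:, list(ANNOTATION_COLUMNS)]
        annotations["sample_id"] = annotations["sample_id"].astype(str)
        annotations["condition"] = annotations["condition"].astype(str)
        annotations["timepoint"] = annotations["timepoint"].astype(str)
        try:
            annotations["replicate"] = annotations["replicate"].astype(int)
        except (TypeError, ValueError) as exc:
            raise FormatError("replicate must be an integer") from exc
        if (annotations["replicate"] < 1).any():
            raise FormatError("replicate numbers must be positive")
        if annotations["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in annotations")
        ann_ids = set(annotations["sample_id"])
        col_ids = set(data.columns)
        if ann_ids != col_ids:
            raise FormatError(
                "annotation/sample mismatch: "
                f"only-in-annotations={sorted(ann_ids - col_ids)}, "
                f"only-in-table={sorted(col_ids - ann_ids)}"
            )
        annotations = (
            annotations.set_index("sample_id").loc[list(data.columns)].reset_index()
        )
        self.data = data
        self.annotations = annotations

    # -- convenience accessors -------------------------------------------------

    @property
    def proteins(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def condition_of(self) -> dict[str, str]:
        return dict(zip(self.annotations["sample_id"], self.annotations["condition"]))

    def samples_where(self, condition: str | None = None, timepoint: str | None = None) -> list[str]:
        ann = self.annotations
        mask = pd.Series(True, index=ann.index)
        if condition is not None:
            mask &= ann["condition"] == condition
        if timepoint is not None:
            mask &= ann["timepoint"] == timepoint
        return list(ann.loc[mask, "sample_id"])

    def annotation_records(self) -> list[SampleAnnotation]:
        return [SampleAnnotation(**rec) for rec in self.annotations.to_dict("records")]

    def with_data(self, data: pd.DataFrame) -> "AbundanceTable":
        return AbundanceTable(data, self.annotations)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        n, m = self.shape
        return f"AbundanceTable({n} proteins x {m} samples)"


def read_abundance_table(path, annotation_path) -> AbundanceTable:
    """Read an abundance TSV plus its sample-annotation sidecar."""
    try:
        data = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=list(MISSING_TOKENS),
            keep_default_na=False,
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse abundance table {path}: {exc}") from exc
    try:
        data = data.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance value in {path}: {exc}") from exc
    try:
        annotations = pd.read_csv(annotation_path, sep="\t", dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse annotation table {annotation_path}: {exc}") from exc
    return AbundanceTable(data, annotations)


def write_abundance_table(table: AbundanceTable, path, annotation_path) -> None:
    data = table.data.copy()
    data.to_csv(path, sep="\t", na_rep="NA")
    table.annotations.to_csv(annotation_path, sep="\t", index=False)


# -- gene sets (GMT) ----------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset


class GeneSetCollection(Mapping):
    """Mapping from set id to :class:`GeneSet`; member ids are uppercase."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.set_id in self._sets:
                raise FormatError(f"duplicate gene-set id {gs.set_id!r}")
            if not gs.members:
                raise FormatError(f"gene set {gs.set_id!r} has no members")
            members = frozenset(str(m).upper() for m in gs.members)
            self._sets[gs.set_id] = GeneSet(gs.set_id, gs.description, members)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def members(self, set_id: str) -> frozenset:
        return self._sets[set_id].members

    def all_members(self) -> frozenset:
        out: set = set()
        for gs in self._sets.values():
            out |= gs.members
        return frozenset(out)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set collection; members are uppercased and deduplicated."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_id, description, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            sets.append(GeneSet(set_id, description, frozenset(members)))
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id in sorted(collection):
            gs = collection[set_id]
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.members)]) + "\n")


# -- interactome --------------------------------------------------------------


def read_edge_list(path) -> nx.Graph:
    """Read a 2-column edge list or 3-column SIF into an undirected simple graph.

    Self-loops are dropped (node kept) with a warning; duplicate and reversed
    edges collapse.
    """
    graph = nx.Graph()
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 2:
                a, b = fields
            elif len(fields) == 3:
                a, _, b = fields
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 (edge list) or 3 (SIF) fields, got {len(fields)}"
                )
            n_lines += 1
            a, b = a.upper(), b.upper()
            if a == b:
                warnings.warn(f"self-loop on {a!r} dropped (node retained)")
                graph.add_node(a)
            else:
                graph.add_edge(a, b)
    if n_lines == 0:
        raise FormatError(f"{path}: empty edge list")
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        # isolated nodes are not representable in an edge list; callers that
        # need them must carry a node list separately
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


# -- generic result tables ----------------------------------------------------


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, Mapping):
            rows.append(dict(rec))
        else:
            raise DataError(f"cannot serialize record of type {type(rec).__name__}")
    return pd.DataFrame(rows)


def write_results(records, path, columns: list[str] | None = None, json_mirror: bool = False):
    """Write a flat result table as TSV with a deterministic sorted row order.

    Rows are sorted by the first column (the primary key), remaining columns
    breaking ties; sets/frozensets are serialized as comma-joined sorted tokens.
    """
    frame = _as_frame(records)
    if columns is not None:
        if frame.empty and not len(frame.columns):
            frame = pd.DataFrame(columns=columns)
        else:
            frame = frame.loc[:, columns]
    for col in frame.columns:
        if frame[col].map(lambda v: isinstance(v, (set, frozenset))).any():
            frame[col] = frame[col].map(
                lambda v: ",".join(sorted(v)) if isinstance(v, (set, frozenset)) else v
            )
    if len(frame.columns) and len(frame):
        frame = frame.sort_values(by=list(frame.columns), kind="mergesort")
    path = Path(path)
    try:
        frame.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise DataError(f"cannot write results to {path}: {exc}") from exc
    if json_mirror:
        with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
            json.dump(frame.to_dict("records"), fh, indent=2, sort_keys=True, default=str)
    return path
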