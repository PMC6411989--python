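"""Diagnosis-table I/O and projection into ontology views.

A cohort is a set of mice, each belonging to an inbred strain, with sex
and study-group metadata and zero or more necropsy diagnoses.  Each
diagnosis names an anatomical site and a pathological process.  Mice
without any diagnosis are "healthy" and, for every ontology view, are
annotated with that view's root class so that similarity and enrichment
stay defined for them.

Six views exist: the two source ontologies (MA, MPATH) and the four
compound pattern ontologies (MAP, MAPT, PAM, PAMT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ontology import OntologyGraph, UnknownClassError
from .patterns import CombinedOntology

__all__ = [
    "DiagnosisRecord",
    "Cohort",
    "AnnotationView",
    "VIEWS",
    "load_diagnoses",
    "project_annotations",
    "split_groups",
]

VIEWS = ("MA", "MPATH", "MAP", "MAPT", "PAM", "PAMT")

DIAGNOSIS_COLUMNS = ["mouse_id", "strain", "sex", "group", "anatomy_id", "pathology_id"]
MOUSE_COLUMNS = ["mouse_id", "strain", "sex", "group"]


@dataclass(frozen=True)
class DiagnosisRecord:
    mouse_id: str
    strain: str
    sex: str
    group: str
    anatomy_id: str
    pathology_id: str


@dataclass
class Cohort:
    """Mice with metadata plus their (possibly empty) diagnosis records."""

    mice: dict[str, tuple[str, str, str]]  # mouse_id -> (strain, sex, group)
    records: list[DiagnosisRecord]
    excluded_strains: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.mouse_id not in self.mice:
                raise ValueError(f"record for unknown mouse {rec.mouse_id!r}")

    @property
    def n_mice(self) -> int:
        return len(self.mice)

    def strains(self) -> list[str]:
        return sorted({s for s, _, _ in self.mice.values()})

    def strain_of(self, mouse_id: str) -> str:
        return self.mice[mouse_id][0]

    def mouse_ids(self) -> list[str]:
        return sorted(self.mice)

    def records_by_mouse(self) -> dict[str, list[DiagnosisRecord]]:
        out: dict[str, list[DiagnosisRecord]] = {m: [] for m in self.mice}
        for rec in self.records:
            out[rec.mouse_id].append(rec)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.mouse_id, r.strain, r.sex, r.group, r.anatomy_id, r.pathology_id)
                for r in self.records
            ],
            columns=DIAGNOSIS_COLUMNS,
        )

    def write_tsv(self, diagnoses_path, mouse_table_path=None) -> None:
        self.to_frame().to_csv(diagnoses_path, sep="\t", index=False)
        if mouse_table_path is not None:
            rows = [(m, s, x, g) for m, (s, x, g) in sorted(self.mice.items())]
            pd.DataFrame(rows, columns=MOUSE_COLUMNS).to_csv(
                mouse_table_path, sep="\t", index=False
            )


@dataclass
class AnnotationView:
    """A cohort's annotations projected into one ontology view."""

    view: str
    graph: OntologyGraph
    annotations: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}; expected one of {VIEWS}")
        for mouse, classes in self.annotations.items():
            if not classes:
                raise ValueError(f"mouse {mouse!r} has an empty annotation set")

    @property
    def mouse_ids(self) -> list[str]:
        return sorted(self.annotations)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s): {missing}")


def load_diagnoses(
    path,
    mouse_table=None,
    exclude_strains: Iterable[str] = (),
    exclude_groups: Iterable[str] = (),
    column_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a diagnosis TSV (plus optional mouse table) into a Cohort.

    ``column_map`` renames external column names onto the canonical ones
    (``mouse_id, strain, sex, group, anatomy_id, pathology_id``), which
    lets database exports be consumed without preprocessing.  Mice listed
    in ``mouse_table`` but absent from the diagnosis file are kept as
    healthy, record-less mice.  ``exclude_strains``/``exclude_groups``
    drop whole strains or study arms before anything else is computed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    _require_columns(df, DIAGNOSIS_COLUMNS, "diagnosis table")
    bad = df[DIAGNOSIS_COLUMNS].isna().any(axis=1)
    if bad.any():
        # +2: header line and 1-based numbering
        raise ValueError(f"malformed diagnosis row at line {int(bad.idxmax()) + 2}")

    mice: dict[str, tuple[str, str, str]] = {}
    for row in df.itertuples(index=False):
        meta = (row.strain, row.sex, row.group)
        prev = mice.setdefault(row.mouse_id, meta)
        if prev != meta:
            raise ValueError(f"inconsistent metadata for mouse {row.mouse_id!r}")

    if mouse_table is not None:
        mt = pd.read_csv(mouse_table, sep="\t", dtype=str)
        if column_map:
            mt = mt.rename(columns=dict(column_map))
        _require_columns(mt, MOUSE_COLUMNS, "mouse table")
        for row in mt.itertuples(index=False):
            meta = (row.strain, row.sex, row.group)
            prev = mice.setdefault(row.mouse_id, meta)
            if prev != meta:
                raise ValueError(f"inconsistent metadata for mouse {row.mouse_id!r}")

    exclude_strains = set(exclude_strains)
    exclude_groups = set(exclude_groups)
    known_strains = {s for s, _, _ in mice.values()}
    for s in exclude_strains - known_strains:
        warnings.warn(f"excluded strain {s!r} not present in the data", stacklevel=2)

    mice = {
        m: meta
        for m, meta in mice.items()
        if meta[0] not in exclude_strains and meta[2] not in exclude_groups
    }
    records = [
        DiagnosisRecord(*row)
        for row in df[DIAGNOSIS_COLUMNS].itertuples(index=False)
        if row.mouse_id in mice
    ]
    return Cohort(mice=mice, records=records, excluded_strains=exclude_strains)


def project_annotations(
    cohort: Cohort,
    view: str,
    anatomy: OntologyGraph | None = None,
    pathology: OntologyGraph | None = None,
    combined: Mapping[str, CombinedOntology] | CombinedOntology | None = None,
) -> AnnotationView:
    """Project the cohort's diagnoses into one ontology view.

    MA keeps anatomy IDs, MPATH keeps pathology IDs, and the pattern
    views map each (anatomy, pathology) pair to its compound class in
    the corresponding combined ontology.  Duplicate annotations collapse;
    healthy mice are annotated with the view graph's root.
    """
    if view not in VIEWS:
        raise ValueError(f"unknown view {view!r}")
    if view == "MA":
        if anatomy is None:
            raise ValueError("MA view needs the anatomy graph")
        graph = anatomy
        mapper = lambda rec: rec.anatomy_id  # noqa: E731
    elif view == "MPATH":
        if pathology is None:
            raise ValueError("MPATH view needs the pathology graph")
        graph = pathology
        mapper = lambda rec: rec.pathology_id  # noqa: E731
    else:
        if isinstance(combined, CombinedOntology):
            co = combined
        elif combined is not None and view in combined:
            co = combined[view]
        else:
            raise ValueError(f"view {view!r} needs its CombinedOntology")
        if co.kind.value != view:
            raise ValueError(f"combined ontology is {co.kind.value}, not {view}")
        graph = co.backbone

        def mapper(rec):
            pair = (rec.anatomy_id, rec.pathology_id)
            try:
                return co.class_for_pair[pair]
            except KeyError:
                raise UnknownClassError(
                    f"pair {pair!r} absent from the {view} ontology"
                ) from None

    annotations: dict[str, set[str]] = {m: set() for m in cohort.mice}
    for rec in cohort.records:
        cid = mapper(rec)
        if cid not in graph.classes:
            raise UnknownClassError(f"class {cid!r} not in {view} graph")
        annotations[rec.mouse_id].add(cid)
    for m, classes in annotations.items():
        if not classes:
            classes.add(graph.root)
    return AnnotationView(
        view=view,
        graph=graph,
        annotations={m: frozenset(c) for m, c in annotations.items()},
    )


def split_groups(cohort: Cohort) -> dict[tuple[str, str], list[str]]:
    """Partition mouse IDs by (group, sex), each list sorted."""
    out: dict[tuple[str, str], list[str]] = {}
    for mouse_id, (_, sex, group) in cohort.mice.items():
        out.setdefault((group, sex), []).append(mouse_id)
    return {k: sorted(v) for k, v in sorted(out.items())}
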