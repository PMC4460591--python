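"""Readers and writers for the knowledge-base bundle and standard formats.

A KB bundle is a directory holding ``manifest.yaml`` (feature types,
categories, declared cardinalities, ontology file names), ``items.tsv``,
``associations.tsv``, ``ppis.tsv`` and one ``.obo`` file per ontology-typed
characteristic.  TSV dialect: UTF-8, one header row, tab-separated, no
quoting; evidence codes pipe-separated; empty string for missing optional
values.  Loading enforces every model invariant, so downstream modules can
assume a valid KB.  Saving then loading reproduces a semantically identical
KB, and output rows are sorted so serialization is byte-stable.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional

import obonet
import yaml

from .model import (
    Association,
    Category,
    FeatureItem,
    FeatureType,
    Inferred,
    KBValidationError,
    KnowledgeBase,
    PPIRecord,
    SemanticType,
)
from .ontology import OntologyDAG
from .transfer import TransferredAnnotation

_ITEM_COLS = ["item_id", "feature_type", "obsolete", "item_class", "source"]
_ASSOC_COLS = ["subject_id", "object_id", "semantic_type", "evidence_codes",
               "source", "inferred", "obsolete"]
_PPI_COLS = ["ppi_id", "protein_1_id", "protein_2_id", "source", "obsolete"]
_TRANSFER_COLS = ["subject_id", "subject_type", "semantic_type", "object_id",
                  "object_type", "inferred", "candidate_only", "evidence",
                  "provenance_edge_1", "provenance_edge_2"]


class LoadError(KBValidationError):
    """A bundle file failed to parse or validate; names file and row."""


def _bool(text: str, where: str) -> bool:
    if text in ("true", "True", "1"):
        return True
    if text in ("false", "False", "0", ""):
        return False
    raise LoadError(f"{where}: malformed boolean {text!r}")


def _enum(cls, text: str, where: str):
    try:
        return cls(text)
    except ValueError:
        raise LoadError(f"{where}: malformed {cls.__name__} value {text!r}") \
            from None


# ----------------------------------------------------------------- OBO files

def read_obo(path, name: str = "") -> OntologyDAG:
    """Minimal OBO 1.2 subset: [Term] stanzas with id, name, is_a,
    is_obsolete; other tags are ignored (delegates to obonet)."""
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    dag = OntologyDAG(name=name or str(path))
    for term, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        dag.add_term(term, obsolete=obsolete, name=data.get("name", ""))
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            dag.add_is_a(child, parent)
    dag.validate()
    return dag


def write_obo(dag: OntologyDAG, path, name: Optional[str] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {name or dag.name or 'ontology'}\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\n")
            if dag.term_names.get(term):
                fh.write(f"name: {dag.term_names[term]}\n")
            for parent in sorted(dag.parents(term)):
                fh.write(f"is_a: {parent}\n")
            if term in dag.obsolete:
                fh.write("is_obsolete: true\n")


# ---------------------------------------------------------------- KB bundles

def write_kb(kb: KnowledgeBase, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "feature_types": [
            {"name": t.name, "category": t.category.value,
             "is_ontology": t.is_ontology,
             **({"ontology_file": f"{t.name}.obo"} if t.is_ontology else {})}
            for t in sorted(kb.feature_types.values(), key=lambda t: t.name)],
        "cardinalities": [
            {"subject_type": s, "semantic_type": st.value, "object_type": o,
             "cardinality": c}
            for (s, st, o), c in sorted(kb.cardinalities.items(),
                                        key=lambda kv: (kv[0][0],
                                                        kv[0][1].value,
                                                        kv[0][2]))],
    }
    with open(path / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    with open(path / "items.tsv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ITEM_COLS)
        for item in sorted(kb.items.values(),
                           key=lambda i: (i.feature_type, i.item_id)):
            w.writerow([item.item_id, item.feature_type,
                        str(item.obsolete).lower(), item.item_class or "",
                        item.source])
    with open(path / "associations.tsv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ASSOC_COLS)
        for a in sorted(kb.associations, key=Association.sort_key):
            w.writerow([a.subject_id, a.object_id, a.semantic_type.value,
                        "|".join(sorted(a.evidence_codes)), a.source,
                        a.inferred.value, str(a.obsolete).lower()])
    with open(path / "ppis.tsv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PPI_COLS)
        for ppi in sorted(kb.ppis.values(), key=lambda p: p.ppi_id):
            w.writerow([ppi.ppi_id, ppi.protein_1_id, ppi.protein_2_id,
                        ppi.source, str(ppi.obsolete).lower()])
    for name, dag in kb.ontologies.items():
        write_obo(dag, path / f"{name}.obo", name=name)


def _read_rows(path: Path, expected_cols: list[str]):
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != expected_cols:
            raise LoadError(f"{path.name}: expected columns {expected_cols}, "
                            f"got {header}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(expected_cols):
                raise LoadError(f"{path.name}:{lineno}: expected "
                                f"{len(expected_cols)} columns, got {len(row)}")
            yield lineno, row


def read_kb(path) -> KnowledgeBase:
    path = Path(path)
    manifest_path = path / "manifest.yaml"
    if not manifest_path.exists():
        raise LoadError(f"{path}: no manifest.yaml")
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    kb = KnowledgeBase()
    for spec in manifest.get("feature_types", []):
        ftype = FeatureType(spec["name"],
                            _enum(Category, spec["category"], "manifest"),
                            bool(spec.get("is_ontology", False)))
        ontology = None
        if ftype.is_ontology:
            obo_path = path / spec.get("ontology_file", f"{ftype.name}.obo")
            ontology = read_obo(obo_path, name=ftype.name)
        kb.add_feature_type(ftype, ontology=ontology)
    for spec in manifest.get("cardinalities", []):
        kb.declare_cardinality(
            spec["subject_type"],
            _enum(SemanticType, spec["semantic_type"], "manifest"),
            spec["object_type"], spec["cardinality"])
    from .model import UnknownItemError
    for lineno, row in _read_rows(path / "items.tsv", _ITEM_COLS):
        where = f"items.tsv:{lineno}"
        try:
            kb.add_item(FeatureItem(row[0], row[1], _bool(row[2], where),
                                    row[3] or None, row[4]))
        except (KBValidationError, UnknownItemError) as exc:
            raise LoadError(f"{where}: {exc}") from None
    for lineno, row in _read_rows(path / "associations.tsv", _ASSOC_COLS):
        where = f"associations.tsv:{lineno}"
        evidence = frozenset(c for c in row[3].split("|") if c)
        try:
            kb.add_association(Association(
                row[0], row[1], _enum(SemanticType, row[2], where),
                evidence, row[4], _enum(Inferred, row[5], where),
                _bool(row[6], where)))
        except (KBValidationError, UnknownItemError) as exc:
            raise LoadError(f"{where}: {exc}") from None
    ppi_path = path / "ppis.tsv"
    if ppi_path.exists():
        for lineno, row in _read_rows(ppi_path, _PPI_COLS):
            where = f"ppis.tsv:{lineno}"
            try:
                kb.add_ppi(PPIRecord.make(row[0], row[1], row[2], row[3],
                                          _bool(row[4], where)))
            except (KBValidationError, UnknownItemError) as exc:
                raise LoadError(f"{where}: {exc}") from None
    kb.validate()
    return kb


# ----------------------------------------------------------------- GAF files

def read_gaf(path, protein_type: str = "protein",
             source: str = "GAF") -> list[Association]:
    """GAF 2.x subset: column 2 = object id, 4 = qualifier, 5 = ontology
    term, 7 = evidence code.  NOT-qualified rows are skipped; duplicate
    (object, term) rows merge their evidence codes."""
    merged: dict[tuple[str, str], set[str]] = {}
    order: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 7:
                raise LoadError(f"{path}:{lineno}: GAF row has {len(cols)} "
                                "columns, need at least 7")
            object_id, qualifier, term, evidence = cols[1], cols[3], cols[4], cols[6]
            if "NOT" in qualifier.split("|"):
                continue
            key = (object_id, term)
            if key not in merged:
                merged[key] = set()
                order.append(key)
            if evidence:
                merged[key].add(evidence)
    return [Association(obj, term, SemanticType.ANNOTATED_TO,
                        frozenset(merged[(obj, term)]), source=source)
            for obj, term in order]


def write_gaf(annotations: Iterable[Association], path, db: str = "transannot",
              aspect: str = "F", date: str = "19700101") -> None:
    """Minimal 17-column GAF 2.x rows for transferred ontology annotations;
    column 6 (DB:Reference) carries the TRANSITIVE_RELATIONSHIP marker and
    column 7 the union of support evidence codes."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.1\n")
        for a in sorted(annotations, key=Association.sort_key):
            evidence = "|".join(sorted(a.evidence_codes)) or "IEA"
            row = [db, a.subject_id, a.subject_id, "", a.object_id,
                   "TRANSITIVE_RELATIONSHIP", evidence, "", aspect, "", "",
                   "protein", "taxon:0", date, db, "", ""]
            fh.write("\t".join(row) + "\n")


# ----------------------------------------------------------- transfer output

def _edge_repr(a: Association) -> str:
    return f"{a.subject_id}|{a.semantic_type.value}|{a.object_id}|{a.source}"


def write_transfers(kb: KnowledgeBase, transfers: Iterable[TransferredAnnotation],
                    path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TRANSFER_COLS)
        for t in transfers:
            a = t.association
            w.writerow([
                a.subject_id, kb.items[a.subject_id].feature_type,
                a.semantic_type.value,
                a.object_id, kb.items[a.object_id].feature_type,
                a.inferred.value, str(t.candidate_only).lower(),
                "|".join(sorted(a.evidence_codes)),
                ";".join(_edge_repr(ab) for ab, _ in t.provenance),
                ";".join(_edge_repr(bc) for _, bc in t.provenance),
            ])
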