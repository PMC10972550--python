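"""Identifier annotations, evidence sentences and curation-guideline checks.

Identifier annotations pair a BioModels qualifier (``bqbiol:is``,
``bqmodel:isDescribedBy``, ...) with an Identifiers.org namespace prefix and
an accession validated against the namespace's pattern. The namespace
registry is a bundled, versioned snapshot (tab-separated ``prefix, pattern,
name``); a different snapshot can be loaded from any file with the same
layout.

Evidence sentences carry optional publication provenance (PMID / PMCID /
DOI) and can be attached to one or many element paths, including the fact
root. Publication metadata resolution is delegated to a pluggable provider;
the default provider is an offline table of synthetic records.

The compliance checker reports, per reaction, the four minimum-information
rules for causal molecular-interaction statements (MI2CAST): source and
target entities, interaction effect (SBO term), evidence provenance, and —
as a recommendation only — biological context.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Optional

from .core import Fact, ROOT_PATH, element_core, touch
from .errors import (
    AccessionError,
    ConflictError,
    DanglingReferenceError,
    FormatError,
    RegistryError,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .audit import AuditLog

_PMID_RE = re.compile(r"^\d+$")
_PMCID_RE = re.compile(r"^PMC\d+$")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("factcurator").joinpath("data", name)))


def load_qualifiers(path: str | Path | None = None) -> frozenset[str]:
    """Closed BioModels qualifier vocabulary, from the bundled data file."""
    p = Path(path) if path else _data_path("biomodels_qualifiers.txt")
    tokens = []
    for line in p.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            tokens.append(line)
    return frozenset(tokens)


BIOMODELS_QUALIFIERS = load_qualifiers()


@dataclass(frozen=True)
class IdentifierAnnotation:
    """One database cross-reference on an element."""

    qualifier: str
    namespace_prefix: str
    accession: str

    @property
    def uri(self) -> str:
        return f"identifiers.org/{self.namespace_prefix}:{self.accession}"


class NamespaceRegistry:
    """Snapshot of Identifiers.org namespace prefixes and accession patterns."""

    def __init__(self, entries: Mapping[str, dict], snapshot_version: str) -> None:
        self.entries = dict(entries)
        self.snapshot_version = snapshot_version

    def __contains__(self, prefix: str) -> bool:
        return prefix in self.entries

    def pattern(self, prefix: str) -> re.Pattern:
        try:
            return self.entries[prefix]["compiled"]
        except KeyError:
            raise RegistryError(f"unknown namespace prefix {prefix!r}") from None

    def check(self, prefix: str, accession: str) -> None:
        """Raise unless ``prefix`` is registered and ``accession`` matches its pattern."""
        pat = self.pattern(prefix)
        if not pat.match(accession):
            raise AccessionError(
                f"accession {accession!r} does not match pattern for namespace {prefix!r}"
            )

    @classmethod
    def from_file(cls, path: str | Path, snapshot_version: str | None = None) -> "NamespaceRegistry":
        text = Path(path).read_text(encoding="utf-8")
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise FormatError("registry snapshot is empty")
        header = lines[0].split("\t")
        if header[:3] != ["prefix", "pattern", "name"]:
            raise FormatError("registry snapshot must start with header 'prefix\\tpattern\\tname'")
        entries = {}
        for ln in lines[1:]:
            prefix, pattern, name = ln.split("\t")[:3]
            entries[prefix] = {"pattern": pattern, "name": name, "compiled": re.compile(pattern)}
        return cls(entries, snapshot_version or Path(path).stem)


_default_registry: NamespaceRegistry | None = None


def default_registry() -> NamespaceRegistry:
    """The bundled registry snapshot (loaded once per process)."""
    global _default_registry
    if _default_registry is None:
        _default_registry = NamespaceRegistry.from_file(
            _data_path("registry_snapshot.tsv"), snapshot_version="2024-03"
        )
    return _default_registry


@dataclass(frozen=True)
class PublicationRef:
    """Publication provenance: a DOI, PubMed or PubMed Central identifier."""

    id_type: str  # "doi" | "pmid" | "pmcid"
    id_value: str
    metadata: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.id_type == "pmid":
            ok = bool(_PMID_RE.match(self.id_value))
        elif self.id_type == "pmcid":
            ok = bool(_PMCID_RE.match(self.id_value))
        elif self.id_type == "doi":
            ok = self.id_value.startswith("10.")
        else:
            raise FormatError(f"unknown publication id type {self.id_type!r}")
        if not ok:
            raise FormatError(f"malformed {self.id_type} value {self.id_value!r}")

    def key(self) -> tuple[str, str]:
        return (self.id_type, self.id_value)


@dataclass
class SentenceEvidence:
    """A literature sentence attached to one or more elements of a fact."""

    evidence_id: str
    sentence: str
    source_kind: str = "external"  # "knowledgebase" | "external"
    provenance: Optional[PublicationRef] = None
    attached_to: set[str] = field(default_factory=set)


# -- metadata providers ----------------------------------------------------


class FixtureMetadataProvider:
    """Offline publication-metadata table (synthetic records, for tests/demos)."""

    def __init__(self, path: str | Path | None = None) -> None:
        p = Path(path) if path else _data_path("publications_synthetic.tsv")
        self._table: dict[tuple[str, str], dict] = {}
        lines = p.read_text(encoding="utf-8").splitlines()
        header = lines[0].split("\t")
        for ln in lines[1:]:
            if not ln.strip():
                continue
            row = dict(zip(header, ln.split("\t")))
            self._table[(row["id_type"], row["id_value"])] = {
                "title": row["title"],
                "journal": row["journal"],
                "year": int(row["year"]),
                "authors": row["authors"].split("; "),
            }

    def lookup(self, id_type: str, id_value: str) -> Optional[dict]:
        return self._table.get((id_type, id_value))


class EmptyMetadataProvider:
    def lookup(self, id_type: str, id_value: str) -> Optional[dict]:
        return None


def resolve_publication_metadata(
    ref: PublicationRef, resolver=None
) -> tuple[PublicationRef, bool]:
    """Fill ``ref.metadata`` from a provider; never raises on lookup failure.

    Returns ``(ref_with_metadata, resolved)``. Format errors in the
    identifier itself are raised by :class:`PublicationRef` before lookup.
    """
    provider = resolver if resolver is not None else FixtureMetadataProvider()
    try:
        meta = provider.lookup(ref.id_type, ref.id_value)
    except Exception:
        meta = None
    if meta is None:
        return ref, False
    return replace(ref, metadata=meta), True


# -- operations ------------------------------------------------------------


def annotate_element(
    fact: Fact,
    element_path: str,
    qualifier: str,
    prefix: str,
    accession: str,
    registry: NamespaceRegistry | None = None,
    *,
    actor: str = "system",
    log: Optional["AuditLog"] = None,
) -> Fact:
    """Attach an identifier annotation to the element at ``element_path``."""
    registry = registry or default_registry()
    if qualifier not in BIOMODELS_QUALIFIERS:
        raise ValidationError(f"{qualifier!r} is not a BioModels qualifier")
    registry.check(prefix, accession)
    element = fact.resolve_path(element_path)
    ann = IdentifierAnnotation(qualifier=qualifier, namespace_prefix=prefix, accession=accession)
    core = element_core(element)
    if ann in core.identifier_annotations:
        raise ConflictError(f"duplicate annotation {qualifier} {ann.uri} on {element_path}")
    core.identifier_annotations.append(ann)
    touch(fact, element)
    if log is not None:
        log.append(
            author=actor,
            verb="annotated",
            fact_key=fact.draft_uuid,
            target=element_path,
            comment=f"{qualifier} {ann.uri}",
        )
    return fact


def _next_evidence_id(fact: Fact) -> str:
    n = 0
    for ev_id in fact.evidences:
        m = re.match(r"^ev(\d+)$", ev_id)
        if m:
            n = max(n, int(m.group(1)))
    return f"ev{n + 1}"


def attach_sentence(
    fact: Fact,
    sentence: str,
    element_paths: Iterable[str],
    provenance: Optional[PublicationRef] = None,
    source_kind: str = "external",
    *,
    evidence_id: str | None = None,
    actor: str = "system",
    log: Optional["AuditLog"] = None,
) -> tuple[Fact, str]:
    """Store a sentence evidence and attach it to every listed element path.

    Re-attaching an identical (sentence, provenance) pair merges the new
    paths into the existing evidence instead of duplicating it.
    """
    paths = list(element_paths)
    if not sentence or not sentence.strip():
        raise ValidationError("evidence sentence must be non-empty")
    if not paths:
        raise ValidationError("evidence must be attached to at least one path")
    if source_kind not in ("knowledgebase", "external"):
        raise ValidationError(f"unknown source_kind {source_kind!r}")
    targets = [fact.resolve_path(p) for p in paths]  # raises on dangling path

    prov_key = provenance.key() if provenance else None
    existing = None
    for ev in fact.evidences.values():
        ev_key = ev.provenance.key() if ev.provenance else None
        if ev.sentence == sentence and ev_key == prov_key:
            existing = ev
            break

    if existing is not None:
        ev = existing
        ev.attached_to.update(paths)
    else:
        ev = SentenceEvidence(
            evidence_id=evidence_id or _next_evidence_id(fact),
            sentence=sentence,
            source_kind=source_kind,
            provenance=provenance,
            attached_to=set(paths),
        )
        if ev.evidence_id in fact.evidences:
            raise ConflictError(f"evidence id {ev.evidence_id!r} already used")
        fact.evidences[ev.evidence_id] = ev

    for element in targets:
        element_core(element).evidence_refs.add(ev.evidence_id)
    touch(fact, *targets)
    if log is not None:
        log.append(
            author=actor,
            verb="evidence_added",
            fact_key=fact.draft_uuid,
            target=sorted(ev.attached_to)[0],
            comment=f"evidence {ev.evidence_id} on {len(ev.attached_to)} path(s)",
        )
    return fact, ev.evidence_id


# -- MI2CAST compliance ----------------------------------------------------


def _has_provenanced_evidence(fact: Fact, core) -> bool:
    return any(
        ev_id in fact.evidences and fact.evidences[ev_id].provenance is not None
        for ev_id in core.evidence_refs
    )


def validate_mi2cast(fact: Fact) -> dict:
    """Per-reaction minimum-information compliance report.

    rule1_entities: the reaction has a source (>=1 reactant or modifier) and
    a target (>=1 product). rule2_effect: the reaction carries an SBO term
    typing the interaction. rule3_evidence: the reaction or the fact root has
    at least one evidence with publication provenance. rule4_context
    (advisory): an enclosing compartment of the participants is annotated,
    or every participating species carries an identifier annotation.

    ``overall`` per reaction and for the fact requires rules 1-3 only;
    rule 4 is reported as a recommendation.
    """
    reactions = []
    root_ok = _has_provenanced_evidence(fact, fact.core)
    for r in fact.reactions:
        rule1 = bool((r.reactants or r.modifiers) and r.products)
        rule2 = r.core.sbo_term is not None
        rule3 = root_ok or _has_provenanced_evidence(fact, r.core) or any(
            _has_provenanced_evidence(fact, sr.core) for sr in r.participants()
        )
        participating = []
        compartments = set()
        for sr in r.participants():
            for s in fact.species:
                if s.core.local_id == sr.species_ref:
                    participating.append(s)
                    compartments.add(s.compartment_ref)
        comp_annotated = any(
            c.core.identifier_annotations
            for c in fact.compartments
            if c.core.local_id in compartments
        )
        species_annotated = bool(participating) and all(
            s.core.identifier_annotations for s in participating
        )
        rule4 = comp_annotated or species_annotated
        reactions.append(
            {
                "reaction": r.core.local_id,
                "rule1_entities": rule1,
                "rule2_effect": rule2,
                "rule3_evidence": rule3,
                "rule4_context": rule4,
                "overall": rule1 and rule2 and rule3,
            }
        )
    return {
        "reactions": reactions,
        "overall": bool(reactions) and all(r["overall"] for r in reactions),
    }
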