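"""Fact data model: an SBML-aligned element hierarchy with a shared annotatable core.

A *fact* is the minimal curated unit of systems-biology knowledge — species
enclosed in compartments, connected by one or more reactions — where every
element (including the fact root and every per-participant species
reference) embeds the same :class:`AnnotatableCore`, so identifier
annotations, notes and evidence can be attached at any level.

Elements are addressed by slash paths::

    /                              the fact root
    /compartment:cytosol
    /species:tp53
    /reaction:r1
    /reaction:r1/reactant:r1_sr1   a per-participant species reference

Mutating operations require a draft fact, strictly advance ``updated_on`` of
the touched element and of the root, and emit exactly one audit record when
an audit log is supplied.
"""

from __future__ import annotations

import re
import uuid
from dataclasses import dataclass, field
from datetime import datetime
from typing import TYPE_CHECKING, Iterator, Optional, Sequence, Union

from . import clock
from .errors import (
    ConflictError,
    DanglingReferenceError,
    DependencyError,
    ImmutabilityError,
    NotFoundError,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .annotation import IdentifierAnnotation, SentenceEvidence
    from .audit import AuditLog

SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
SBO_RE = re.compile(r"^SBO:\d{7}$")

ROOT_PATH = "/"
ROLES = ("reactant", "product", "modifier")


@dataclass
class Note:
    """Free-text (or opaque imported XML) note attached to an element."""

    text: str
    author: str = "system"
    kind: str = "text"  # "text" | "opaque_xml"
    created_on: datetime = field(default_factory=clock.now)


@dataclass
class AnnotatableCore:
    """Shared annotatable state embedded in every element of a fact."""

    local_id: str
    display_name: str = ""
    sbo_term: Optional[str] = None
    identifier_annotations: list["IdentifierAnnotation"] = field(default_factory=list)
    notes: list[Note] = field(default_factory=list)
    evidence_refs: set[str] = field(default_factory=set)
    created_on: datetime = field(default_factory=clock.now)
    updated_on: datetime = field(default_factory=clock.now)

    def __post_init__(self) -> None:
        if self.updated_on < self.created_on:
            self.updated_on = self.created_on


def new_core(local_id: str, name: str = "", sbo_term: str | None = None) -> AnnotatableCore:
    t = clock.now()
    return AnnotatableCore(
        local_id=local_id,
        display_name=name,
        sbo_term=sbo_term,
        created_on=t,
        updated_on=t,
    )


@dataclass
class Compartment:
    core: AnnotatableCore


@dataclass
class Species:
    core: AnnotatableCore
    compartment_ref: str = ""


@dataclass
class SpeciesReference:
    """One participant slot of a reaction (reactant, product or modifier)."""

    core: AnnotatableCore
    species_ref: str = ""
    role: str = "reactant"
    stoichiometry: float = 1.0


@dataclass
class Reaction:
    core: AnnotatableCore
    reactants: list[SpeciesReference] = field(default_factory=list)
    products: list[SpeciesReference] = field(default_factory=list)
    modifiers: list[SpeciesReference] = field(default_factory=list)
    reversible: bool = False

    def participants(self) -> Iterator[SpeciesReference]:
        yield from self.reactants
        yield from self.products
        yield from self.modifiers


@dataclass
class Fact:
    """A versionable collection of compartments, species and reactions."""

    core: AnnotatableCore
    title: str
    group_ref: str
    visibility: str = "private"
    status: str = "draft"  # "draft" | "released" (snapshot objects only)
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    evidences: dict[str, "SentenceEvidence"] = field(default_factory=dict)
    base_identifier: Optional[str] = None
    draft_uuid: str = field(default_factory=lambda: uuid.uuid4().hex)

    # -- element addressing ------------------------------------------------

    def iter_elements(self) -> Iterator[tuple[str, object]]:
        """Yield (path, element) for the root and every nested element."""
        yield ROOT_PATH, self
        for c in self.compartments:
            yield f"/compartment:{c.core.local_id}", c
        for s in self.species:
            yield f"/species:{s.core.local_id}", s
        for r in self.reactions:
            rp = f"/reaction:{r.core.local_id}"
            yield rp, r
            for kind, members in (
                ("reactant", r.reactants),
                ("product", r.products),
                ("modifier", r.modifiers),
            ):
                for sr in members:
                    yield f"{rp}/{kind}:{sr.core.local_id}", sr

    def all_local_ids(self) -> list[str]:
        return [e.core.local_id for p, e in self.iter_elements() if p != ROOT_PATH]

    def resolve_path(self, path: str):
        """Return the element at ``path`` or raise :class:`DanglingReferenceError`."""
        for p, e in self.iter_elements():
            if p == path:
                return e
        raise DanglingReferenceError(f"no element at path {path!r}")

    def has_path(self, path: str) -> bool:
        return any(p == path for p, _ in self.iter_elements())

    def find_element(self, local_id: str) -> tuple[str, object]:
        for p, e in self.iter_elements():
            if p != ROOT_PATH and e.core.local_id == local_id:
                return p, e
        raise NotFoundError(f"no element with local_id {local_id!r}")

    def get_compartment(self, local_id: str) -> Compartment:
        for c in self.compartments:
            if c.core.local_id == local_id:
                return c
        raise DanglingReferenceError(f"compartment {local_id!r} not found")

    def get_species(self, local_id: str) -> Species:
        for s in self.species:
            if s.core.local_id == local_id:
                return s
        raise DanglingReferenceError(f"species {local_id!r} not found")

    def get_reaction(self, local_id: str) -> Reaction:
        for r in self.reactions:
            if r.core.local_id == local_id:
                return r
        raise NotFoundError(f"reaction {local_id!r} not found")


def element_core(element: object) -> AnnotatableCore:
    return element.core  # every element type embeds exactly one core


# -- internal helpers ------------------------------------------------------


def touch(fact: Fact, *elements: object) -> None:
    """Strictly advance updated_on of the given elements and of the root."""
    t = clock.now()
    for e in elements:
        element_core(e).updated_on = t
    fact.core.updated_on = t


def _require_draft(fact: Fact) -> None:
    if fact.status != "draft":
        raise ImmutabilityError(
            "fact is a released snapshot; only drafts can be edited"
        )


def _require_new_id(fact: Fact, local_id: str) -> None:
    if not SID_RE.match(local_id or ""):
        raise ValidationError(f"{local_id!r} is not a valid SId")
    if local_id in fact.all_local_ids():
        raise ConflictError(f"local_id {local_id!r} already used in this fact")


def _record(
    log: Optional["AuditLog"],
    fact: Fact,
    actor: str,
    verb: str,
    target: str,
    comment: str,
) -> None:
    if log is not None:
        log.append(author=actor, verb=verb, fact_key=fact.draft_uuid, target=target, comment=comment)


# -- operations ------------------------------------------------------------


def create_fact(
    title: str,
    group_ref: str,
    visibility: str = "private",
    *,
    actor: str = "system",
    log: Optional["AuditLog"] = None,
) -> Fact:
    """Create an empty draft fact owned by ``group_ref``."""
    if not title or not title.strip():
        raise ValidationError("fact title must be non-empty")
    if visibility not in ("private", "public"):
        raise ValidationError(f"unknown visibility {visibility!r}")
    fact = Fact(core=new_core("fact", name=title), title=title, group_ref=group_ref, visibility=visibility)
    _record(log, fact, actor, "created", ROOT_PATH, f"created fact {title!r}")
    return fact


def add_compartment(
    fact: Fact,
    local_id: str,
    name: str = "",
    *,
    sbo_term: str | None = None,
    actor: str = "system",
    log: Optional["AuditLog"] = None,
) -> Fact:
    _require_draft(fact)
    _require_new_id(fact, local_id)
    _check_sbo(sbo_term)
    comp = Compartment(core=new_core(local_id, name, sbo_term))
    fact.compartments.append(comp)
    touch(fact, comp)
    _record(log, fact, actor, "updated", f"/compartment:{local_id}", f"added compartment {local_id}")
    return fact


def add_species(
    fact: Fact,
    local_id: str,
    name: str,
    compartment_ref: str,
    *,
    sbo_term: str | None = None,
    actor: str = "system",
    log: Optional["AuditLog"] = None,
) -> Fact:
    _require_draft(fact)
    _require_new_id(fact, local_id)
    _check_sbo(sbo_term)
    fact.get_compartment(compartment_ref)  # raises if dangling
    sp = Species(core=new_core(local_id, name, sbo_term), compartment_ref=compartment_ref)
    fact.species.append(sp)
    touch(fact, sp)
    _record(log, fact, actor, "updated", f"/species:{local_id}", f"added species {local_id}")
    return fact


ParticipantRef = Union[str, tuple]


def _as_participant(ref: ParticipantRef) -> tuple[str, float]:
    if isinstance(ref, str):
        return ref, 1.0
    species_ref, stoichiometry = ref
    return species_ref, float(stoichiometry)


def _check_sbo(sbo_term: str | None) -> None:
    if sbo_term is not None and not SBO_RE.match(sbo_term):
        raise ValidationError(f"sbo_term {sbo_term!r} does not match SBO:0000000 form")


def add_reaction(
    fact: Fact,
    local_id: str,
    reactant_refs: Sequence[ParticipantRef],
    product_refs: Sequence[ParticipantRef],
    modifier_refs: Sequence[ParticipantRef] = (),
    sbo_term: str | None = None,
    reversible: bool = False,
    *,
    actor: str = "system",
    log: Optional["AuditLog"] = None,
) -> Fact:
    """Append a reaction whose participants reference existing species.

    Each participant gets its own :class:`SpeciesReference` with a fresh
    annotatable core (id ``<reaction>_sr<N>``) so that annotation can target
    individual participation, not just the species.
    """
    _require_draft(fact)
    _require_new_id(fact, local_id)
    _check_sbo(sbo_term)
    if not reactant_refs and not product_refs:
        raise ValidationError("a reaction needs at least one reactant or product")
    rxn = Reaction(core=new_core(local_id, sbo_term=sbo_term), reversible=reversible)
    counter = 0
    used = set(fact.all_local_ids()) | {local_id}
    for role, refs, target_list in (
        ("reactant", reactant_refs, rxn.reactants),
        ("product", product_refs, rxn.products),
        ("modifier", modifier_refs, rxn.modifiers),
    ):
        for ref in refs:
            species_ref, stoich = _as_participant(ref)
            fact.get_species(species_ref)  # raises if dangling
            if stoich <= 0:
                raise ValidationError("stoichiometry must be > 0")
            counter += 1
            sr_id = f"{local_id}_sr{counter}"
            while sr_id in used:
                counter += 1
                sr_id = f"{local_id}_sr{counter}"
            used.add(sr_id)
            target_list.append(
                SpeciesReference(
                    core=new_core(sr_id),
                    species_ref=species_ref,
                    role=role,
                    stoichiometry=1.0 if role == "modifier" else stoich,
                )
            )
    fact.reactions.append(rxn)
    touch(fact, rxn)
    _record(log, fact, actor, "updated", f"/reaction:{local_id}", f"added reaction {local_id}")
    return fact


def _drop_evidence_paths(fact: Fact, paths: set[str]) -> None:
    """Detach evidences from removed paths; drop evidences left with no path."""
    dead: list[str] = []
    for ev_id, ev in fact.evidences.items():
        ev.attached_to -= paths
        if not ev.attached_to:
            dead.append(ev_id)
    for ev_id in dead:
        del fact.evidences[ev_id]
        for _, e in fact.iter_elements():
            element_core(e).evidence_refs.discard(ev_id)


def remove_element(
    fact: Fact,
    local_id: str,
    *,
    actor: str = "system",
    log: Optional["AuditLog"] = None,
) -> Fact:
    """Remove an element by local_id.

    Removing a species cascades to its species references; removing a
    compartment that still encloses species is refused.
    """
    _require_draft(fact)
    path, element = fact.find_element(local_id)
    removed_paths = {path}

    if isinstance(element, Compartment):
        dependants = [s.core.local_id for s in fact.species if s.compartment_ref == local_id]
        if dependants:
            raise DependencyError(
                f"compartment {local_id!r} still encloses species {dependants}"
            )
        fact.compartments.remove(element)
    elif isinstance(element, Species):
        fact.species.remove(element)
        for r in fact.reactions:
            rp = f"/reaction:{r.core.local_id}"
            for kind, members in (
                ("reactant", r.reactants),
                ("product", r.products),
                ("modifier", r.modifiers),
            ):
                for sr in list(members):
                    if sr.species_ref == local_id:
                        members.remove(sr)
                        removed_paths.add(f"{rp}/{kind}:{sr.core.local_id}")
    elif isinstance(element, Reaction):
        fact.reactions.remove(element)
        removed_paths |= {
            f"{path}/{sr.role}:{sr.core.local_id}" for sr in element.participants()
        }
    elif isinstance(element, SpeciesReference):
        parent_path = path.rsplit("/", 1)[0]
        rxn = fact.resolve_path(parent_path)
        for members in (rxn.reactants, rxn.products, rxn.modifiers):
            if element in members:
                members.remove(element)
    else:  # pragma: no cover - exhaustive over element types
        raise NotFoundError(f"cannot remove element at {path}")

    _drop_evidence_paths(fact, removed_paths)
    touch(fact)
    _record(log, fact, actor, "updated", path, f"removed element {local_id}")
    return fact


# -- validation ------------------------------------------------------------


def validate_fact(fact: Fact) -> list[dict]:
    """Structural validation report: list of {severity, path, message}.

    The report contains no ``error`` entries iff all fact invariants hold and
    every reaction has at least one reactant or product. Isolated species
    (not participating in any reaction) are reported as warnings only.
    """
    report: list[dict] = []

    def err(path: str, message: str, severity: str = "error") -> None:
        report.append({"severity": severity, "path": path, "message": message})

    seen: dict[str, str] = {}
    for path, element in fact.iter_elements():
        if path == ROOT_PATH:
            continue
        lid = element.core.local_id
        if not SID_RE.match(lid or ""):
            err(path, f"local_id {lid!r} is not a valid SId")
        if lid in seen:
            err(path, f"duplicate local_id {lid!r} (also at {seen[lid]})")
        else:
            seen[lid] = path

    compartment_ids = {c.core.local_id for c in fact.compartments}
    species_ids = {s.core.local_id for s in fact.species}

    for s in fact.species:
        if s.compartment_ref not in compartment_ids:
            err(
                f"/species:{s.core.local_id}",
                f"species references unknown compartment {s.compartment_ref!r}",
            )

    used_species: set[str] = set()
    for r in fact.reactions:
        rp = f"/reaction:{r.core.local_id}"
        if not r.reactants and not r.products:
            err(rp, "reaction has neither reactants nor products")
        for kind, members in (
            ("reactant", r.reactants),
            ("product", r.products),
            ("modifier", r.modifiers),
        ):
            for sr in members:
                sp = f"{rp}/{kind}:{sr.core.local_id}"
                if sr.role != kind:
                    err(sp, f"role {sr.role!r} does not match list {kind!r}")
                if sr.species_ref not in species_ids:
                    err(sp, f"references unknown species {sr.species_ref!r}")
                else:
                    used_species.add(sr.species_ref)
                if sr.stoichiometry <= 0:
                    err(sp, "stoichiometry must be > 0")

    if not fact.reactions:
        err(ROOT_PATH, "releasable fact requires >=1 reaction")

    if fact.status == "released" and not fact.base_identifier:
        err(ROOT_PATH, "released fact lacks a base identifier")

    valid_paths = {p for p, _ in fact.iter_elements()}
    for ev_id, ev in fact.evidences.items():
        if not ev.attached_to:
            err(ROOT_PATH, f"evidence {ev_id} attached to no path")
        for p in ev.attached_to:
            if p not in valid_paths:
                err(ROOT_PATH, f"evidence {ev_id} attached to unknown path {p!r}")
            else:
                if ev_id not in element_core(fact.resolve_path(p)).evidence_refs:
                    err(p, f"evidence {ev_id} not cross-referenced by element")
    for path, element in fact.iter_elements():
        for ev_id in element_core(element).evidence_refs:
            if ev_id not in fact.evidences:
                err(path, f"element references unknown evidence {ev_id!r}")
            elif path not in fact.evidences[ev_id].attached_to:
                err(path, f"evidence {ev_id} does not list path {path!r}")

    for s in sorted(species_ids - used_species):
        err(f"/species:{s}", "species participates in no reaction", severity="warning")

    report.sort(key=lambda e: (e["path"], e["severity"], e["message"]))
    return report


def fact_is_valid(fact: Fact) -> bool:
    """True iff :func:`validate_fact` reports no error-severity entries."""
    return not any(e["severity"] == "error" for e in validate_fact(fact))
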