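"""JSON codecs for the on-disk repository store.

The store is plain text by design (diff-able, transparent): drafts and
repository state are JSON, release content is the canonical SBML document
plus a sorted evidence bundle, and the audit log is append-only TSV.
"""

from __future__ import annotations

from datetime import datetime, timedelta
from typing import Optional

from .annotation import IdentifierAnnotation, PublicationRef, SentenceEvidence
from .basket import Basket, BasketItem
from .collaboration import EditLock, Group, Role, User
from .core import (
    AnnotatableCore,
    Compartment,
    Fact,
    Note,
    Reaction,
    Species,
    SpeciesReference,
)
from .review import Task, Vote


def _dt(t: datetime) -> str:
    return t.isoformat()


def _parse_dt(s: str) -> datetime:
    return datetime.fromisoformat(s)


def core_to_dict(core: AnnotatableCore) -> dict:
    return {
        "local_id": core.local_id,
        "display_name": core.display_name,
        "sbo_term": core.sbo_term,
        "identifier_annotations": [
            {"qualifier": a.qualifier, "prefix": a.namespace_prefix, "accession": a.accession}
            for a in core.identifier_annotations
        ],
        "notes": [
            {"text": n.text, "author": n.author, "kind": n.kind, "created_on": _dt(n.created_on)}
            for n in core.notes
        ],
        "evidence_refs": sorted(core.evidence_refs),
        "created_on": _dt(core.created_on),
        "updated_on": _dt(core.updated_on),
    }


def core_from_dict(d: dict) -> AnnotatableCore:
    return AnnotatableCore(
        local_id=d["local_id"],
        display_name=d.get("display_name", ""),
        sbo_term=d.get("sbo_term"),
        identifier_annotations=[
            IdentifierAnnotation(a["qualifier"], a["prefix"], a["accession"])
            for a in d.get("identifier_annotations", [])
        ],
        notes=[
            Note(
                text=n["text"],
                author=n.get("author", "system"),
                kind=n.get("kind", "text"),
                created_on=_parse_dt(n["created_on"]),
            )
            for n in d.get("notes", [])
        ],
        evidence_refs=set(d.get("evidence_refs", [])),
        created_on=_parse_dt(d["created_on"]),
        updated_on=_parse_dt(d["updated_on"]),
    )


def publication_to_dict(p: Optional[PublicationRef]) -> Optional[dict]:
    if p is None:
        return None
    return {"id_type": p.id_type, "id_value": p.id_value, "metadata": p.metadata}


def publication_from_dict(d: Optional[dict]) -> Optional[PublicationRef]:
    if d is None:
        return None
    return PublicationRef(d["id_type"], d["id_value"], d.get("metadata"))


def evidence_to_dict(ev: SentenceEvidence) -> dict:
    return {
        "evidence_id": ev.evidence_id,
        "sentence": ev.sentence,
        "source_kind": ev.source_kind,
        "provenance": publication_to_dict(ev.provenance),
        "attached_to": sorted(ev.attached_to),
    }


def evidence_from_dict(d: dict) -> SentenceEvidence:
    return SentenceEvidence(
        evidence_id=d["evidence_id"],
        sentence=d["sentence"],
        source_kind=d.get("source_kind", "external"),
        provenance=publication_from_dict(d.get("provenance")),
        attached_to=set(d.get("attached_to", [])),
    )


def _sref_to_dict(sr: SpeciesReference) -> dict:
    return {
        "core": core_to_dict(sr.core),
        "species_ref": sr.species_ref,
        "role": sr.role,
        "stoichiometry": sr.stoichiometry,
    }


def _sref_from_dict(d: dict) -> SpeciesReference:
    return SpeciesReference(
        core=core_from_dict(d["core"]),
        species_ref=d["species_ref"],
        role=d["role"],
        stoichiometry=d.get("stoichiometry", 1.0),
    )


def fact_to_dict(fact: Fact) -> dict:
    return {
        "core": core_to_dict(fact.core),
        "title": fact.title,
        "group_ref": fact.group_ref,
        "visibility": fact.visibility,
        "status": fact.status,
        "base_identifier": fact.base_identifier,
        "draft_uuid": fact.draft_uuid,
        "compartments": [{"core": core_to_dict(c.core)} for c in fact.compartments],
        "species": [
            {"core": core_to_dict(s.core), "compartment_ref": s.compartment_ref}
            for s in fact.species
        ],
        "reactions": [
            {
                "core": core_to_dict(r.core),
                "reversible": r.reversible,
                "reactants": [_sref_to_dict(sr) for sr in r.reactants],
                "products": [_sref_to_dict(sr) for sr in r.products],
                "modifiers": [_sref_to_dict(sr) for sr in r.modifiers],
            }
            for r in fact.reactions
        ],
        "evidences": {k: evidence_to_dict(v) for k, v in sorted(fact.evidences.items())},
    }


def fact_from_dict(d: dict) -> Fact:
    return Fact(
        core=core_from_dict(d["core"]),
        title=d["title"],
        group_ref=d["group_ref"],
        visibility=d.get("visibility", "private"),
        status=d.get("status", "draft"),
        base_identifier=d.get("base_identifier"),
        draft_uuid=d["draft_uuid"],
        compartments=[Compartment(core=core_from_dict(c["core"])) for c in d["compartments"]],
        species=[
            Species(core=core_from_dict(s["core"]), compartment_ref=s["compartment_ref"])
            for s in d["species"]
        ],
        reactions=[
            Reaction(
                core=core_from_dict(r["core"]),
                reversible=r.get("reversible", False),
                reactants=[_sref_from_dict(x) for x in r["reactants"]],
                products=[_sref_from_dict(x) for x in r["products"]],
                modifiers=[_sref_from_dict(x) for x in r["modifiers"]],
            )
            for r in d["reactions"]
        ],
        evidences={k: evidence_from_dict(v) for k, v in d.get("evidences", {}).items()},
    )


def group_to_dict(g: Group) -> dict:
    return {
        "group_id": g.group_id,
        "name": g.name,
        "visibility": g.visibility,
        "members": {u: r.name for u, r in sorted(g.members.items())},
    }


def group_from_dict(d: dict) -> Group:
    return Group(
        group_id=d["group_id"],
        name=d["name"],
        visibility=d.get("visibility", "private"),
        members={u: Role[r] for u, r in d.get("members", {}).items()},
    )


def user_to_dict(u: User) -> dict:
    return {"user_id": u.user_id, "display_name": u.display_name}


def task_to_dict(t: Task) -> dict:
    return {
        "task_id": t.task_id,
        "fact_key": t.fact_key,
        "title": t.title,
        "description": t.description,
        "assignees": sorted(t.assignees),
        "status": t.status,
        "votes": {
            u: {"value": v.value, "cast_on": _dt(v.cast_on)} for u, v in sorted(t.votes.items())
        },
        "log": [
            {**e, "timestamp": _dt(e["timestamp"])} for e in t.log
        ],
    }


def task_from_dict(d: dict) -> Task:
    return Task(
        task_id=d["task_id"],
        fact_key=d["fact_key"],
        title=d["title"],
        description=d.get("description", ""),
        assignees=set(d.get("assignees", [])),
        status=d.get("status", "open"),
        votes={
            u: Vote(user_id=u, value=v["value"], cast_on=_parse_dt(v["cast_on"]))
            for u, v in d.get("votes", {}).items()
        },
        log=[{**e, "timestamp": _parse_dt(e["timestamp"])} for e in d.get("log", [])],
    )


def basket_to_dict(b: Basket) -> dict:
    return {
        "owner": b.owner,
        "next_item": b._next_item,
        "items": [
            {
                "item_id": it.item_id,
                "sentence": it.sentence,
                "provenance": publication_to_dict(it.provenance),
                "source_kind": it.source_kind,
                "entity_hints": [list(h) for h in it.entity_hints],
                "selected": it.selected,
            }
            for it in b.items
        ],
    }


def basket_from_dict(d: dict) -> Basket:
    return Basket(
        owner=d["owner"],
        _next_item=d.get("next_item", 1),
        items=[
            BasketItem(
                item_id=it["item_id"],
                sentence=it["sentence"],
                provenance=publication_from_dict(it.get("provenance")),
                source_kind=it.get("source_kind", "external"),
                entity_hints=[tuple(h) for h in it.get("entity_hints", [])],
                selected=it.get("selected", False),
            )
            for it in d.get("items", [])
        ],
    )


def lock_to_dict(lk: EditLock) -> dict:
    return {
        "fact_key": lk.fact_key,
        "holder": lk.holder,
        "acquired_on": _dt(lk.acquired_on),
        "ttl_seconds": lk.ttl.total_seconds(),
    }


def lock_from_dict(d: dict) -> EditLock:
    return EditLock(
        fact_key=d["fact_key"],
        holder=d["holder"],
        acquired_on=_parse_dt(d["acquired_on"]),
        ttl=timedelta(seconds=d.get("ttl_seconds", 1800)),
    )
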