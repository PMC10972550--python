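"""SBML Level 3 serialization of facts, with MIRIAM RDF annotations.

Writing targets Level 3 Version 2 core; reading accepts Level 3 Version 1
or 2. Identifier annotations are emitted as MIRIAM RDF (one
``rdf:Description`` about the element's metaid, one ``rdf:Bag`` per
BioModels qualifier, resources as ``https://identifiers.org/<prefix>:<acc>``
URIs). Evidence sentences are embedded in each attached element's
``annotation`` under a dedicated XML namespace, keeping the MIRIAM block
readable by standard tools. Legacy ``urn:miriam:`` URNs are accepted on
read and normalized to the identifiers.org form.

Export is canonical: a pure function of fact content (timestamps, group and
audit data excluded), with attributes and siblings written in a fixed,
sorted order, so identical facts serialize to byte-identical documents.
"""

from __future__ import annotations

import re
import warnings
from typing import Optional
from urllib.parse import unquote

from lxml import etree

from .annotation import (
    IdentifierAnnotation,
    NamespaceRegistry,
    PublicationRef,
    SentenceEvidence,
    default_registry,
)
from .core import (
    AnnotatableCore,
    Compartment,
    Fact,
    Note,
    Reaction,
    ROOT_PATH,
    SID_RE,
    Species,
    SpeciesReference,
    element_core,
    fact_is_valid,
    new_core,
    validate_fact,
)
from .errors import SbmlParseError, UnsupportedLevelError, ValidationError

SBML_L3V2_NS = "http://www.sbml.org/sbml/level3/version2/core"
SBML_L3V1_NS = "http://www.sbml.org/sbml/level3/version1/core"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
BQMODEL_NS = "http://biomodels.net/model-qualifiers/"
XHTML_NS = "http://www.w3.org/1999/xhtml"
EVIDENCE_NS = "https://factcurator.dev/ns/evidence/1"

_QUALIFIER_NS = {"bqbiol": BQBIOL_NS, "bqmodel": BQMODEL_NS}
_NS_QUALIFIER = {v: k for k, v in _QUALIFIER_NS.items()}

NSMAP = {
    None: SBML_L3V2_NS,
    "rdf": RDF_NS,
    "bqbiol": BQBIOL_NS,
    "bqmodel": BQMODEL_NS,
    "fc": EVIDENCE_NS,
}

_IDENTIFIERS_URI_RE = re.compile(
    r"^https?://identifiers\.org/(?:(?P<p1>[^/:]+)[:/](?P<a1>.+))$"
)
_MIRIAM_URN_RE = re.compile(r"^urn:miriam:(?P<prefix>[^:]+):(?P<acc>.+)$")


class SbmlImportWarning(UserWarning):
    """Non-fatal problem while importing a third-party SBML document."""


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) and tag.startswith("{") else str(tag)


def _meta_id(local_id: str) -> str:
    return f"meta_{local_id}"


def _fmt_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _evidence_sort_key(ev_id: str):
    m = re.match(r"^ev(\d+)$", ev_id)
    return (0, int(m.group(1)), "") if m else (1, 0, ev_id)


# -- export ----------------------------------------------------------------


def export_sbml(fact: Fact) -> str:
    """Serialize a valid fact to a canonical SBML L3V2 document (text)."""
    report = validate_fact(fact)
    errors = [e for e in report if e["severity"] == "error"]
    if errors:
        first = errors[0]
        raise ValidationError(
            f"fact fails validation ({len(errors)} error(s); first: "
            f"{first['path']}: {first['message']})"
        )

    root = etree.Element(f"{{{SBML_L3V2_NS}}}sbml", nsmap=NSMAP)
    root.set("level", "3")
    root.set("version", "2")
    model = etree.SubElement(root, f"{{{SBML_L3V2_NS}}}model")
    model.set("id", "fact")
    model.set("metaid", _meta_id("fact"))
    if fact.title:
        model.set("name", fact.title)
    if fact.core.sbo_term:
        model.set("sboTerm", fact.core.sbo_term)
    _write_core_children(model, fact, fact.core, ROOT_PATH)

    if fact.compartments:
        loc = etree.SubElement(model, f"{{{SBML_L3V2_NS}}}listOfCompartments")
        for c in fact.compartments:
            el = etree.SubElement(loc, f"{{{SBML_L3V2_NS}}}compartment")
            el.set("id", c.core.local_id)
            _set_core_attrs(el, c.core)
            el.set("constant", "true")
            _write_core_children(el, fact, c.core, f"/compartment:{c.core.local_id}")

    if fact.species:
        los = etree.SubElement(model, f"{{{SBML_L3V2_NS}}}listOfSpecies")
        for s in fact.species:
            el = etree.SubElement(los, f"{{{SBML_L3V2_NS}}}species")
            el.set("id", s.core.local_id)
            el.set("compartment", s.compartment_ref)
            _set_core_attrs(el, s.core)
            el.set("hasOnlySubstanceUnits", "false")
            el.set("boundaryCondition", "false")
            el.set("constant", "false")
            _write_core_children(el, fact, s.core, f"/species:{s.core.local_id}")

    if fact.reactions:
        lor = etree.SubElement(model, f"{{{SBML_L3V2_NS}}}listOfReactions")
        for r in fact.reactions:
            rp = f"/reaction:{r.core.local_id}"
            el = etree.SubElement(lor, f"{{{SBML_L3V2_NS}}}reaction")
            el.set("id", r.core.local_id)
            _set_core_attrs(el, r.core)
            el.set("reversible", "true" if r.reversible else "false")
            _write_core_children(el, fact, r.core, rp)
            for list_tag, sr_tag, kind, members in (
                ("listOfReactants", "speciesReference", "reactant", r.reactants),
                ("listOfProducts", "speciesReference", "product", r.products),
                ("listOfModifiers", "modifierSpeciesReference", "modifier", r.modifiers),
            ):
                if not members:
                    continue
                lst = etree.SubElement(el, f"{{{SBML_L3V2_NS}}}{list_tag}")
                for sr in members:
                    sre = etree.SubElement(lst, f"{{{SBML_L3V2_NS}}}{sr_tag}")
                    sre.set("id", sr.core.local_id)
                    sre.set("species", sr.species_ref)
                    _set_core_attrs(sre, sr.core)
                    if kind != "modifier":
                        sre.set("stoichiometry", _fmt_number(sr.stoichiometry))
                        sre.set("constant", "true")
                    _write_core_children(
                        sre, fact, sr.core, f"{rp}/{kind}:{sr.core.local_id}"
                    )

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def _set_core_attrs(el, core: AnnotatableCore) -> None:
    el.set("metaid", _meta_id(core.local_id))
    if core.display_name:
        el.set("name", core.display_name)
    if core.sbo_term:
        el.set("sboTerm", core.sbo_term)


def _write_core_children(el, fact: Fact, core: AnnotatableCore, path: str) -> None:
    """Append <notes> and <annotation> (MIRIAM RDF + evidence + opaque blocks)."""
    text_notes = [n for n in core.notes if n.kind == "text"]
    opaque_notes = [n for n in core.notes if n.kind == "opaque_xml"]
    if text_notes:
        notes = etree.SubElement(el, f"{{{SBML_L3V2_NS}}}notes")
        body = etree.SubElement(notes, f"{{{XHTML_NS}}}body", nsmap={None: XHTML_NS})
        for n in text_notes:
            p = etree.SubElement(body, f"{{{XHTML_NS}}}p")
            p.text = n.text

    ev_ids = sorted(core.evidence_refs & set(fact.evidences), key=_evidence_sort_key)
    has_annotation = core.identifier_annotations or ev_ids or opaque_notes
    if not has_annotation:
        return
    ann = etree.SubElement(el, f"{{{SBML_L3V2_NS}}}annotation")

    if core.identifier_annotations:
        rdf = etree.SubElement(ann, f"{{{RDF_NS}}}RDF")
        desc = etree.SubElement(rdf, f"{{{RDF_NS}}}Description")
        desc.set(f"{{{RDF_NS}}}about", f"#{_meta_id(core.local_id)}")
        by_qualifier: dict[str, list[IdentifierAnnotation]] = {}
        for a in core.identifier_annotations:
            by_qualifier.setdefault(a.qualifier, []).append(a)
        for qualifier in sorted(by_qualifier):
            ns_key, local = qualifier.split(":", 1)
            q_el = etree.SubElement(desc, f"{{{_QUALIFIER_NS[ns_key]}}}{local}")
            bag = etree.SubElement(q_el, f"{{{RDF_NS}}}Bag")
            for a in sorted(
                by_qualifier[qualifier], key=lambda a: (a.namespace_prefix, a.accession)
            ):
                li = etree.SubElement(bag, f"{{{RDF_NS}}}li")
                li.set(f"{{{RDF_NS}}}resource", f"https://{a.uri}")

    if ev_ids:
        ev_list = etree.SubElement(ann, f"{{{EVIDENCE_NS}}}evidenceList")
        for ev_id in ev_ids:
            ev = fact.evidences[ev_id]
            ev_el = etree.SubElement(ev_list, f"{{{EVIDENCE_NS}}}evidence")
            ev_el.set("evidenceId", ev.evidence_id)
            ev_el.set("sourceKind", ev.source_kind)
            sent = etree.SubElement(ev_el, f"{{{EVIDENCE_NS}}}sentence")
            sent.text = ev.sentence
            if ev.provenance is not None:
                prov = etree.SubElement(ev_el, f"{{{EVIDENCE_NS}}}provenance")
                prov.set("idType", ev.provenance.id_type)
                prov.set("idValue", ev.provenance.id_value)
                meta = ev.provenance.metadata or {}
                for key in ("title", "journal"):
                    if meta.get(key):
                        prov.set(key, str(meta[key]))
                if meta.get("year"):
                    prov.set("year", str(meta["year"]))
                if meta.get("authors"):
                    prov.set("authors", "; ".join(meta["authors"]))

    for n in opaque_notes:
        try:
            ann.append(etree.fromstring(n.text.encode("utf-8")))
        except etree.XMLSyntaxError:  # stored verbatim but unparsable: keep as comment
            ann.append(etree.Comment(n.text))


# -- import ----------------------------------------------------------------


def import_sbml(
    document: str | bytes,
    group_ref: str,
    registry: NamespaceRegistry | None = None,
    *,
    actor: str = "system",
    log=None,
) -> Fact:
    """Parse an SBML Level 3 document into a new draft fact.

    MIRIAM RDF resources (identifiers.org URIs or legacy ``urn:miriam``
    URNs) become identifier annotations; evidence-namespace payloads become
    sentence evidences; unrecognized annotation content is preserved in
    opaque notes (with a warning) so re-export does not lose it. Species
    without a compartment are placed in an auto-created ``default``
    compartment.
    """
    registry = registry or default_registry()
    data = document.encode("utf-8") if isinstance(document, str) else document
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise SbmlParseError(f"not well-formed XML: {exc}") from exc

    if etree.QName(root).localname != "sbml":
        raise SbmlParseError("root element is not <sbml>")
    ns = etree.QName(root).namespace or ""
    level = root.get("level", "")
    if ns in (SBML_L3V1_NS, SBML_L3V2_NS) or level == "3":
        pass
    elif level in ("1", "2") or "level1" in ns or "level2" in ns:
        raise UnsupportedLevelError(
            f"SBML Level {level or '1/2'} is not supported; re-encode as Level 3"
        )
    else:
        raise SbmlParseError(f"unrecognized SBML namespace {ns!r}")

    model = next((ch for ch in root if _qname_local(ch) == "model"), None)
    if model is None:
        raise SbmlParseError("document has no <model>")

    title = model.get("name") or model.get("id") or "Imported fact"
    fact = Fact(core=new_core("fact", name=title), title=title, group_ref=group_ref)
    if model.get("sboTerm"):
        fact.core.sbo_term = model.get("sboTerm")

    used_ids: set[str] = set()

    def fresh_id(candidate: str | None, stem: str) -> str:
        lid = candidate if candidate and SID_RE.match(candidate) else None
        n = 0
        while lid is None or lid in used_ids:
            n += 1
            lid = f"{stem}{n}"
        used_ids.add(lid)
        return lid

    def ensure_default_compartment() -> str:
        if not any(c.core.local_id == "default" for c in fact.compartments):
            used_ids.add("default")
            fact.compartments.append(Compartment(core=new_core("default", "default")))
        return "default"

    pending: list[tuple[etree._Element, AnnotatableCore, str]] = []
    pending.append((model, fact.core, ROOT_PATH))

    for xc in _find_list(model, "listOfCompartments", "compartment"):
        lid = fresh_id(xc.get("id"), "c")
        comp = Compartment(core=_core_from(xc, lid))
        fact.compartments.append(comp)
        pending.append((xc, comp.core, f"/compartment:{lid}"))

    for xs in _find_list(model, "listOfSpecies", "species"):
        lid = fresh_id(xs.get("id"), "s")
        comp_ref = xs.get("compartment")
        if not comp_ref:
            comp_ref = ensure_default_compartment()
        elif not any(c.core.local_id == comp_ref for c in fact.compartments):
            warnings.warn(
                f"species {lid!r} references undeclared compartment {comp_ref!r}",
                SbmlImportWarning,
                stacklevel=2,
            )
            comp_ref = ensure_default_compartment()
        sp = Species(core=_core_from(xs, lid), compartment_ref=comp_ref)
        fact.species.append(sp)
        pending.append((xs, sp.core, f"/species:{lid}"))

    for xr in _find_list(model, "listOfReactions", "reaction"):
        lid = fresh_id(xr.get("id"), "r")
        rxn = Reaction(
            core=_core_from(xr, lid), reversible=xr.get("reversible") == "true"
        )
        fact.reactions.append(rxn)
        rp = f"/reaction:{lid}"
        pending.append((xr, rxn.core, rp))
        for list_name, kind, members in (
            ("listOfReactants", "reactant", rxn.reactants),
            ("listOfProducts", "product", rxn.products),
            ("listOfModifiers", "modifier", rxn.modifiers),
        ):
            for xsr in _find_list(xr, list_name, None):
                species_ref = xsr.get("species") or ""
                sr_id = fresh_id(xsr.get("id"), f"{lid}_sr")
                stoich = float(xsr.get("stoichiometry", "1") or "1")
                sr = SpeciesReference(
                    core=_core_from(xsr, sr_id),
                    species_ref=species_ref,
                    role=kind,
                    stoichiometry=stoich if kind != "modifier" else 1.0,
                )
                members.append(sr)
                pending.append((xsr, sr.core, f"{rp}/{kind}:{sr_id}"))

    for xel, core, path in pending:
        _read_notes(xel, core)
        _read_annotation(xel, core, path, fact, registry)

    for ev in fact.evidences.values():
        for p in ev.attached_to:
            element_core(fact.resolve_path(p)).evidence_refs.add(ev.evidence_id)

    if log is not None:
        log.append(
            author=actor,
            verb="imported",
            fact_key=fact.draft_uuid,
            target=ROOT_PATH,
            comment=f"imported SBML document ({len(fact.species)} species, "
            f"{len(fact.reactions)} reaction(s))",
        )
    return fact


def _qname_local(el) -> str:
    if not isinstance(el.tag, str):
        return ""
    return etree.QName(el).localname


def _find_list(parent, list_name: str, child_name: str | None):
    for ch in parent:
        if _qname_local(ch) == list_name:
            for item in ch:
                if child_name is None or _qname_local(item) == child_name:
                    if isinstance(item.tag, str):
                        yield item


def _core_from(xel, local_id: str) -> AnnotatableCore:
    return new_core(local_id, name=xel.get("name") or "", sbo_term=xel.get("sboTerm"))


def _read_notes(xel, core: AnnotatableCore) -> None:
    for notes in (ch for ch in xel if _qname_local(ch) == "notes"):
        for p in notes.iter(f"{{{XHTML_NS}}}p"):
            text = "".join(p.itertext()).strip()
            if text:
                core.notes.append(Note(text=text, kind="text"))


def parse_identifier_uri(resource: str) -> Optional[tuple[str, str]]:
    """(prefix, accession) from an identifiers.org URI or urn:miriam URN."""
    m = _MIRIAM_URN_RE.match(resource)
    if m:
        return m.group("prefix").lower(), unquote(m.group("acc"))
    m = _IDENTIFIERS_URI_RE.match(resource)
    if m:
        return m.group("p1").lower(), unquote(m.group("a1"))
    return None


def _read_annotation(
    xel, core: AnnotatableCore, path: str, fact: Fact, registry: NamespaceRegistry
) -> None:
    for ann in (ch for ch in xel if _qname_local(ch) == "annotation"):
        for child in ann:
            if not isinstance(child.tag, str):
                continue
            qn = etree.QName(child)
            if qn.namespace == RDF_NS and qn.localname == "RDF":
                _read_rdf(child, core, path, registry)
            elif qn.namespace == EVIDENCE_NS and qn.localname == "evidenceList":
                _read_evidence_list(child, path, fact)
            else:
                warnings.warn(
                    f"unrecognized annotation content <{qn.localname}> "
                    f"(namespace {qn.namespace!r}) at {path}; preserved verbatim",
                    SbmlImportWarning,
                    stacklevel=2,
                )
                core.notes.append(
                    Note(text=etree.tostring(child).decode("utf-8").strip(), kind="opaque_xml")
                )


def _read_rdf(rdf_el, core: AnnotatableCore, path: str, registry: NamespaceRegistry) -> None:
    for desc in rdf_el.iter(f"{{{RDF_NS}}}Description"):
        for q_el in desc:
            if not isinstance(q_el.tag, str):
                continue
            qn = etree.QName(q_el)
            if qn.namespace not in _NS_QUALIFIER:
                warnings.warn(
                    f"unknown qualifier namespace {qn.namespace!r} at {path}; preserved",
                    SbmlImportWarning,
                    stacklevel=2,
                )
                core.notes.append(
                    Note(text=etree.tostring(q_el).decode("utf-8").strip(), kind="opaque_xml")
                )
                continue
            qualifier = f"{_NS_QUALIFIER[qn.namespace]}:{qn.localname}"
            for li in q_el.iter(f"{{{RDF_NS}}}li"):
                resource = li.get(f"{{{RDF_NS}}}resource") or ""
                parsed = parse_identifier_uri(resource)
                if parsed is None:
                    warnings.warn(
                        f"unparsable annotation resource {resource!r} at {path}; preserved",
                        SbmlImportWarning,
                        stacklevel=2,
                    )
                    core.notes.append(Note(text=resource, kind="opaque_xml"))
                    continue
                prefix, accession = parsed
                if prefix not in registry:
                    warnings.warn(
                        f"unknown namespace prefix {prefix!r} at {path}; kept as note",
                        SbmlImportWarning,
                        stacklevel=2,
                    )
                    core.notes.append(Note(text=resource, kind="opaque_xml"))
                    continue
                if not registry.pattern(prefix).match(accession):
                    warnings.warn(
                        f"accession {accession!r} does not match the {prefix!r} pattern",
                        SbmlImportWarning,
                        stacklevel=2,
                    )
                ann = IdentifierAnnotation(
                    qualifier=qualifier, namespace_prefix=prefix, accession=accession
                )
                if ann not in core.identifier_annotations:
                    core.identifier_annotations.append(ann)


def _read_evidence_list(list_el, path: str, fact: Fact) -> None:
    for ev_el in list_el.iter(f"{{{EVIDENCE_NS}}}evidence"):
        ev_id = ev_el.get("evidenceId") or None
        sentence = ""
        provenance = None
        for ch in ev_el:
            qn = etree.QName(ch)
            if qn.localname == "sentence":
                sentence = (ch.text or "").strip()
            elif qn.localname == "provenance":
                meta = {}
                if ch.get("title"):
                    meta["title"] = ch.get("title")
                if ch.get("journal"):
                    meta["journal"] = ch.get("journal")
                if ch.get("year"):
                    meta["year"] = int(ch.get("year"))
                if ch.get("authors"):
                    meta["authors"] = ch.get("authors").split("; ")
                provenance = PublicationRef(
                    id_type=ch.get("idType") or "pmid",
                    id_value=ch.get("idValue") or "",
                    metadata=meta or None,
                )
        if not sentence:
            continue
        existing = fact.evidences.get(ev_id) if ev_id else None
        if existing is not None and existing.sentence == sentence:
            existing.attached_to.add(path)
            continue
        if ev_id is None or ev_id in fact.evidences:
            n = len(fact.evidences)
            ev_id = f"ev{n + 1}"
            while ev_id in fact.evidences:
                n += 1
                ev_id = f"ev{n + 1}"
        fact.evidences[ev_id] = SentenceEvidence(
            evidence_id=ev_id,
            sentence=sentence,
            source_kind=ev_el.get("sourceKind") or "external",
            provenance=provenance,
            attached_to={path},
        )


# -- semantic comparison ---------------------------------------------------


def facts_semantically_equal(a: Fact, b: Fact) -> bool:
    """Equality of curated content (ids, structure, annotations, evidences).

    Canonical export is a pure function of exactly that content, so two
    facts are semantically equal iff their canonical documents are
    byte-identical.
    """
    return export_sbml(a) == export_sbml(b)
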