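"""Evidence-first workflow: collect sentences, bulk-import TSV, checkout facts.

The TSV dialect is deliberately simple: UTF-8, tab-delimited, a required
header line containing at least a ``sentence`` column (optional columns
``pmid``, ``pmcid``, ``doi``, ``source``, ``comment``), no quoting, and no
tabs or newlines inside fields. Provenance is built from the first present
id column in priority order pmid > pmcid > doi. Malformed rows are rejected
individually; the file as a whole is rejected only for a missing or
header-less ``sentence`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

from .annotation import PublicationRef, attach_sentence
from .core import Fact, SID_RE, add_compartment, add_species, create_fact
from .errors import FormatError, NotFoundError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .audit import AuditLog

TSV_COLUMNS = ("sentence", "pmid", "pmcid", "doi", "source", "comment")
_PROVENANCE_PRIORITY = (("pmid", "pmid"), ("pmcid", "pmcid"), ("doi", "doi"))


@dataclass
class BasketItem:
    item_id: str
    sentence: str
    provenance: Optional[PublicationRef] = None
    source_kind: str = "external"
    entity_hints: list[tuple[str, str]] = field(default_factory=list)  # (span, "prefix:accession")
    selected: bool = False


@dataclass
class Basket:
    owner: str
    items: list[BasketItem] = field(default_factory=list)
    _next_item: int = 1

    def _key(self, item: BasketItem):
        prov = item.provenance.key() if item.provenance else None
        return (item.sentence, prov)

    def find(self, item_id: str) -> BasketItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise NotFoundError(f"no basket item {item_id!r}")


def add_to_basket(
    basket: Basket,
    sentence: str,
    provenance: Optional[PublicationRef] = None,
    source_kind: str = "external",
    entity_hints: Iterable[tuple[str, str]] = (),
) -> tuple[Basket, Optional[str]]:
    """Append an item; exact (sentence, provenance) duplicates are skipped.

    Returns (basket, warning) where warning is a message when the item was
    a duplicate and nothing was added.
    """
    if not sentence or not sentence.strip():
        raise ValidationError("basket sentence must be non-empty")
    key = (sentence, provenance.key() if provenance else None)
    for it in basket.items:
        if basket._key(it) == key:
            return basket, f"duplicate of item {it.item_id}; not added"
    item = BasketItem(
        item_id=f"b{basket._next_item}",
        sentence=sentence,
        provenance=provenance,
        source_kind=source_kind,
        entity_hints=list(entity_hints),
    )
    basket._next_item += 1
    basket.items.append(item)
    return basket, None


def import_tsv(basket: Basket, tsv_text: str) -> dict:
    """Bulk-import sentences from TSV text.

    Returns ``{"imported": count, "rejected": [(line_number, reason), ...]}``
    with line numbers counted from 1 (the header is line 1). Row-level
    failures never roll back previously imported rows.
    """
    lines = tsv_text.splitlines()
    if not lines or not lines[0].strip():
        raise FormatError("TSV file has no header line")
    header = lines[0].rstrip("\n").split("\t")
    if "sentence" not in header:
        raise FormatError("TSV header must contain a 'sentence' column")
    col = {name: i for i, name in enumerate(header)}

    imported = 0
    rejected: list[tuple[int, str]] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")

        def get(name: str) -> str:
            i = col.get(name)
            return fields[i].strip() if i is not None and i < len(fields) else ""

        sentence = get("sentence")
        if not sentence:
            rejected.append((lineno, "empty sentence"))
            continue
        provenance = None
        try:
            for column, id_type in _PROVENANCE_PRIORITY:
                value = get(column)
                if value:
                    provenance = PublicationRef(id_type=id_type, id_value=value)
                    break
        except FormatError as exc:
            rejected.append((lineno, str(exc)))
            continue
        source_kind = get("source") or "external"
        if source_kind not in ("knowledgebase", "external"):
            rejected.append((lineno, f"unknown source {source_kind!r}"))
            continue
        basket, warning = add_to_basket(basket, sentence, provenance, source_kind)
        if warning:
            rejected.append((lineno, warning))
        else:
            imported += 1
    return {"imported": imported, "rejected": rejected}


def export_tsv(basket: Basket) -> str:
    """Serialize the basket back to the import dialect (round-trippable)."""
    lines = ["\t".join(("sentence", "pmid", "pmcid", "doi", "source"))]
    for it in basket.items:
        row = {c: "" for c in ("sentence", "pmid", "pmcid", "doi", "source")}
        row["sentence"] = it.sentence.replace("\t", " ").replace("\n", " ")
        row["source"] = it.source_kind
        if it.provenance is not None:
            row[it.provenance.id_type] = it.provenance.id_value
        lines.append("\t".join(row[c] for c in ("sentence", "pmid", "pmcid", "doi", "source")))
    return "\n".join(lines) + "\n"


def _hint_species_id(span: str, used: set[str]) -> str:
    candidate = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in span) or "entity"
    if not SID_RE.match(candidate):
        candidate = f"x_{candidate}"
    base, n = candidate, 1
    while candidate in used:
        n += 1
        candidate = f"{base}_{n}"
    used.add(candidate)
    return candidate


def checkout(
    basket: Basket,
    item_ids: Iterable[str],
    group_ref: str,
    fact_title: str,
    *,
    registry=None,
    actor: str = "system",
    log: Optional["AuditLog"] = None,
) -> Fact:
    """Turn selected basket items into a new draft fact.

    Every selected sentence becomes a root-attached evidence; entity hints
    pre-create species (in an auto-created ``default`` compartment) carrying
    the hinted ``bqbiol:is`` identifier annotations. Selected items are
    consumed from the basket.
    """
    from .annotation import annotate_element  # local import avoids cycle at module load

    ids = list(item_ids)
    if not ids:
        raise ValidationError("checkout requires at least one selected item")
    items = [basket.find(i) for i in ids]

    fact = create_fact(fact_title, group_ref, actor=actor, log=log)
    used_ids: set[str] = set()
    hinted: list[tuple[str, str]] = []
    for it in items:
        for span, identifier in it.entity_hints:
            if (span, identifier) not in hinted:
                hinted.append((span, identifier))
    if hinted:
        add_compartment(fact, "default", "default", actor=actor, log=log)
        for span, identifier in hinted:
            sid = _hint_species_id(span, used_ids)
            add_species(fact, sid, span, "default", actor=actor, log=log)
            prefix, _, accession = identifier.partition(":")
            annotate_element(
                fact, f"/species:{sid}", "bqbiol:is", prefix, accession,
                registry, actor=actor, log=log,
            )
    for it in items:
        attach_sentence(
            fact,
            it.sentence,
            ["/"],
            provenance=it.provenance,
            source_kind=it.source_kind,
            actor=actor,
            log=log,
        )
        basket.items.remove(it)
    return fact
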