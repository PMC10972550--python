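"""Append-only action log: one authored record per successful mutation.

Records are never edited or deleted; linking a record to review tasks only
extends its ``linked_tasks`` set, journalled as an extra line in the
on-disk log so the file itself only ever grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import TYPE_CHECKING, Optional

from . import clock
from .errors import DanglingReferenceError

if TYPE_CHECKING:  # pragma: no cover
    from .core import Fact

VERBS = (
    "created",
    "updated",
    "annotated",
    "evidence_added",
    "evidence_removed",
    "released",
    "deleted",
    "imported",
)


@dataclass
class ActionRecord:
    record_id: int
    author: str
    verb: str
    fact_key: str
    target: str  # element path within the fact ("/" for the root)
    comment: str
    created_on: datetime
    linked_tasks: set[str] = field(default_factory=set)


class AuditLog:
    """In-memory append-only log, optionally journalled to a TSV file."""

    def __init__(self, path: str | Path | None = None) -> None:
        self.records: list[ActionRecord] = []
        self.path = Path(path) if path else None

    def __len__(self) -> int:
        return len(self.records)

    def append(
        self, *, author: str, verb: str, fact_key: str, target: str, comment: str
    ) -> ActionRecord:
        if verb not in VERBS:
            raise ValueError(f"unknown audit verb {verb!r}")
        rec = ActionRecord(
            record_id=len(self.records) + 1,
            author=author,
            verb=verb,
            fact_key=fact_key,
            target=target,
            comment=comment,
            created_on=clock.now(),
        )
        self.records.append(rec)
        self._journal(
            "record",
            str(rec.record_id),
            rec.author,
            rec.verb,
            rec.fact_key,
            rec.target,
            rec.comment,
            rec.created_on.isoformat(),
        )
        return rec

    def _journal(self, *fields: str) -> None:
        if self.path is None:
            return
        safe = [f.replace("\t", " ").replace("\n", " ") for f in fields]
        with self.path.open("a", encoding="utf-8") as fh:
            fh.write("\t".join(safe) + "\n")

    def journal_link(self, record_id: int, task_ids: set[str]) -> None:
        self._journal("link", str(record_id), ",".join(sorted(task_ids)))


def record_action(
    repository,
    author: str,
    verb: str,
    target: str,
    comment: str,
    fact: Optional["Fact"] = None,
) -> ActionRecord:
    """Append one record to the repository log, advancing the touched element.

    ``target`` is an element path when ``fact`` is given, otherwise a fact
    key. The touched element's ``updated_on`` is advanced; ``created_on`` is
    never altered.
    """
    if author not in repository.users:
        raise DanglingReferenceError(f"unknown author {author!r}")
    fact_key = fact.draft_uuid if fact is not None else target
    path = target if fact is not None else "/"
    if fact is not None:
        from .core import touch

        element = fact.resolve_path(path)  # raises on bad path
        touch(fact, element)
    return repository.audit_log.append(
        author=author, verb=verb, fact_key=fact_key, target=path, comment=comment
    )


def link_action_to_tasks(repository, record: ActionRecord, task_ids) -> ActionRecord:
    """Link a record to review tasks (set union; idempotent)."""
    ids = set(task_ids)
    unknown = ids - set(repository.tasks)
    if unknown:
        raise DanglingReferenceError(f"unknown task(s) {sorted(unknown)}")
    record.linked_tasks |= ids
    repository.audit_log.journal_link(record.record_id, ids)
    return record


def element_changelog(
    repository, fact: "Fact", element_path: str | None = None
) -> list[ActionRecord]:
    """Chronological records for a fact, optionally restricted to one subtree."""
    if element_path is not None and not fact.has_path(element_path):
        raise DanglingReferenceError(f"no element at path {element_path!r}")
    out = []
    for rec in repository.audit_log.records:
        if rec.fact_key != fact.draft_uuid:
            continue
        if element_path is None or element_path == "/":
            out.append(rec)
        elif rec.target == element_path or rec.target.startswith(element_path + "/"):
            out.append(rec)
    return out
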