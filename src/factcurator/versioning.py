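"""Stable identifiers, immutable releases, version history and the repository store.

Released facts are published under stable identifiers of the form
``bkc<serial>`` (base) and ``bkc<serial>v<version>`` (versioned). Serials
strictly increase per repository and are never reused, even after a fact is
withdrawn; versions of one fact are consecutive integers starting at 1. The
base form always resolves to the latest release. Each release snapshots the
canonical SBML export plus a sorted evidence bundle, under a SHA-256
content hash that is re-verified on retrieval.

The repository store is a plain-text directory tree::

    <root>/state.json                   users, groups, tasks, baskets, serials
    <root>/drafts/<uuid>.json           editable draft facts
    <root>/releases/bkc<N>/v<M>/content.sbml
    <root>/releases/bkc<N>/v<M>/record.json
    <root>/audit.log                    append-only TSV journal
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional

from . import clock, persistence
from .annotation import validate_mi2cast
from .audit import ActionRecord, AuditLog
from .collaboration import EditLock, Group, User, require_permission
from .core import Fact, validate_fact
from .errors import (
    CurationPermissionError,
    FormatError,
    NotFoundError,
    ValidationError,
)
from .review import Task
from .sbml import export_sbml

IDENTIFIER_RE = re.compile(r"^bkc(?P<serial>\d+)(?:v(?P<version>\d+))?$")


@dataclass(frozen=True)
class StableIdentifier:
    serial: int

    def __post_init__(self) -> None:
        if self.serial < 1:
            raise ValidationError("serial must be a positive integer")

    @property
    def base(self) -> str:
        return f"bkc{self.serial}"

    def version_form(self, version: int) -> str:
        return f"bkc{self.serial}v{version}"


def parse_identifier(identifier: str) -> tuple[int, Optional[int]]:
    """Split ``bkcN[vM]`` into (serial, version-or-None)."""
    m = IDENTIFIER_RE.match(identifier or "")
    if not m:
        raise FormatError(f"malformed stable identifier {identifier!r}")
    version = m.group("version")
    return int(m.group("serial")), (int(version) if version else None)


@dataclass
class Release:
    """Immutable, hashed snapshot of a fact at release time."""

    base: StableIdentifier
    version: int
    content_sbml: str
    evidence_bundle: str  # canonical sorted JSON
    content_hash: str
    release_notes: str
    released_by: str
    released_on: datetime
    mi2cast_report: dict = field(default_factory=dict)
    title: str = ""
    withdrawn: bool = False

    @property
    def identifier(self) -> str:
        return self.base.version_form(self.version)


@dataclass
class VersionHistory:
    base: StableIdentifier
    entries: list[dict]  # {version, released_on, released_by, notes, content_hash}


def content_hash(sbml_text: str, evidence_bundle: str) -> str:
    return hashlib.sha256((sbml_text + evidence_bundle).encode("utf-8")).hexdigest()


def evidence_bundle_of(fact: Fact) -> str:
    bundle = [
        persistence.evidence_to_dict(fact.evidences[k])
        for k in sorted(fact.evidences)
    ]
    return json.dumps(bundle, sort_keys=True, separators=(",", ":"))


class Repository:
    """In-memory repository, optionally backed by a plain-text store."""

    def __init__(self, root: str | Path | None = None) -> None:
        self.root = Path(root) if root else None
        self.users: dict[str, User] = {}
        self.groups: dict[str, Group] = {}
        self.drafts: dict[str, Fact] = {}
        self.releases: dict[int, list[Release]] = {}
        self.withdrawn: set[int] = set()
        self.last_serial = 0
        self.tasks: dict[str, Task] = {}
        self.baskets: dict[str, object] = {}
        self.locks: dict[str, EditLock] = {}
        self.counters: dict[str, int] = {"group": 0, "task": 0}
        self.config: dict = {"quorum": 0.5, "strict_release": False, "lock_ttl_minutes": 30}
        log_path = None
        if self.root is not None:
            self.root.mkdir(parents=True, exist_ok=True)
            log_path = self.root / "audit.log"
        self.audit_log = AuditLog(log_path)

    # -- identity helpers --------------------------------------------------

    def add_user(self, user_id: str, display_name: str = "") -> User:
        if user_id in self.users:
            return self.users[user_id]
        u = User(user_id=user_id, display_name=display_name or user_id)
        self.users[user_id] = u
        return u

    def new_group_id(self) -> str:
        self.counters["group"] += 1
        return f"g{self.counters['group']}"

    def new_task_id(self) -> str:
        self.counters["task"] += 1
        return f"t{self.counters['task']}"

    def group_of(self, fact: Fact) -> Group:
        try:
            return self.groups[fact.group_ref]
        except KeyError:
            raise NotFoundError(f"unknown group {fact.group_ref!r}") from None

    def get_draft(self, key: str) -> Fact:
        try:
            return self.drafts[key]
        except KeyError:
            raise NotFoundError(f"no draft fact {key!r}") from None

    # -- persistence -------------------------------------------------------

    def save(self) -> None:
        if self.root is None:
            return
        from .basket import Basket  # typing only at runtime

        state = {
            "last_serial": self.last_serial,
            "withdrawn": sorted(self.withdrawn),
            "counters": self.counters,
            "config": self.config,
            "users": [persistence.user_to_dict(u) for u in sorted(self.users.values(), key=lambda u: u.user_id)],
            "groups": [persistence.group_to_dict(g) for g in sorted(self.groups.values(), key=lambda g: g.group_id)],
            "tasks": [persistence.task_to_dict(t) for t in sorted(self.tasks.values(), key=lambda t: t.task_id)],
            "baskets": [persistence.basket_to_dict(b) for b in sorted(self.baskets.values(), key=lambda b: b.owner)],
            "locks": [persistence.lock_to_dict(lk) for lk in sorted(self.locks.values(), key=lambda lk: lk.fact_key)],
        }
        (self.root / "state.json").write_text(
            json.dumps(state, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        drafts_dir = self.root / "drafts"
        drafts_dir.mkdir(exist_ok=True)
        keep = set()
        for key, fact in self.drafts.items():
            keep.add(f"{key}.json")
            (drafts_dir / f"{key}.json").write_text(
                json.dumps(persistence.fact_to_dict(fact), indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )
        for stale in drafts_dir.glob("*.json"):
            if stale.name not in keep:
                stale.unlink()

    def _write_release(self, release: Release) -> None:
        if self.root is None:
            return
        rel_dir = self.root / "releases" / release.base.base / f"v{release.version}"
        rel_dir.mkdir(parents=True, exist_ok=True)
        (rel_dir / "content.sbml").write_text(release.content_sbml, encoding="utf-8")
        record = {
            "serial": release.base.serial,
            "version": release.version,
            "evidence_bundle": release.evidence_bundle,
            "content_hash": release.content_hash,
            "release_notes": release.release_notes,
            "released_by": release.released_by,
            "released_on": release.released_on.isoformat(),
            "mi2cast_report": release.mi2cast_report,
            "title": release.title,
            "withdrawn": release.withdrawn,
        }
        (rel_dir / "record.json").write_text(
            json.dumps(record, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def open(cls, root: str | Path) -> "Repository":
        root = Path(root)
        if not (root / "state.json").exists():
            raise NotFoundError(f"no repository at {root} (run init first)")
        repo = cls(root)
        state = json.loads((root / "state.json").read_text(encoding="utf-8"))
        repo.last_serial = state.get("last_serial", 0)
        repo.withdrawn = set(state.get("withdrawn", []))
        repo.counters = state.get("counters", repo.counters)
        repo.config.update(state.get("config", {}))
        for u in state.get("users", []):
            repo.users[u["user_id"]] = User(u["user_id"], u.get("display_name", ""))
        for g in state.get("groups", []):
            group = persistence.group_from_dict(g)
            repo.groups[group.group_id] = group
        for t in state.get("tasks", []):
            task = persistence.task_from_dict(t)
            repo.tasks[task.task_id] = task
        for b in state.get("baskets", []):
            basket = persistence.basket_from_dict(b)
            repo.baskets[basket.owner] = basket
        for lk in state.get("locks", []):
            lock = persistence.lock_from_dict(lk)
            repo.locks[lock.fact_key] = lock
        drafts_dir = root / "drafts"
        if drafts_dir.is_dir():
            for f in sorted(drafts_dir.glob("*.json")):
                fact = persistence.fact_from_dict(json.loads(f.read_text(encoding="utf-8")))
                repo.drafts[fact.draft_uuid] = fact
        releases_dir = root / "releases"
        if releases_dir.is_dir():
            for base_dir in sorted(releases_dir.iterdir()):
                serial, _ = parse_identifier(base_dir.name)
                versions = sorted(
                    (int(v.name[1:]), v) for v in base_dir.iterdir() if v.name.startswith("v")
                )
                for version, vdir in versions:
                    record = json.loads((vdir / "record.json").read_text(encoding="utf-8"))
                    release = Release(
                        base=StableIdentifier(serial),
                        version=version,
                        content_sbml=(vdir / "content.sbml").read_text(encoding="utf-8"),
                        evidence_bundle=record["evidence_bundle"],
                        content_hash=record["content_hash"],
                        release_notes=record["release_notes"],
                        released_by=record["released_by"],
                        released_on=datetime.fromisoformat(record["released_on"]),
                        mi2cast_report=record.get("mi2cast_report", {}),
                        title=record.get("title", ""),
                        withdrawn=record.get("withdrawn", False),
                    )
                    self_list = repo.releases.setdefault(serial, [])
                    self_list.append(release)
        # rebuild the in-memory audit log from the journal
        if (root / "audit.log").exists():
            repo.audit_log.path = None  # avoid re-journalling while replaying
            for line in (root / "audit.log").read_text(encoding="utf-8").splitlines():
                parts = line.split("\t")
                if parts[0] == "record" and len(parts) >= 8:
                    rec = ActionRecord(
                        record_id=int(parts[1]),
                        author=parts[2],
                        verb=parts[3],
                        fact_key=parts[4],
                        target=parts[5],
                        comment=parts[6],
                        created_on=datetime.fromisoformat(parts[7]),
                    )
                    repo.audit_log.records.append(rec)
                elif parts[0] == "link" and len(parts) >= 3:
                    rid = int(parts[1])
                    for rec in repo.audit_log.records:
                        if rec.record_id == rid:
                            rec.linked_tasks |= set(filter(None, parts[2].split(",")))
            repo.audit_log.path = root / "audit.log"
        return repo


# -- operations ------------------------------------------------------------


def mint_identifier(repository: Repository) -> StableIdentifier:
    """Next stable identifier; serials strictly increase and are never reused."""
    repository.last_serial += 1
    return StableIdentifier(repository.last_serial)


def release_fact(
    repository: Repository,
    fact: Fact,
    release_notes: str,
    actor: str,
    *,
    strict: bool | None = None,
) -> Release:
    """Publish an immutable, versioned snapshot of a draft fact.

    The first release mints the base identifier and assigns version 1;
    later releases increment the version. The draft remains editable:
    releases are snapshots, not locks. In strict mode the MI2CAST
    mandatory rules (1-3) gate the release; otherwise failures are only
    recorded in the attached report.
    """
    group = repository.group_of(fact)
    require_permission(group, actor, "release", fact.visibility)
    if not release_notes or not release_notes.strip():
        raise ValidationError("release notes must be non-empty")
    errors = [e for e in validate_fact(fact) if e["severity"] == "error"]
    if errors:
        raise ValidationError(
            f"fact fails validation; first error: {errors[0]['path']}: {errors[0]['message']}"
        )
    report = validate_mi2cast(fact)
    if strict is None:
        strict = bool(repository.config.get("strict_release", False))
    if strict and not report["overall"]:
        raise ValidationError(
            "strict release blocked: MI2CAST mandatory rules (1-3) not satisfied"
        )

    if fact.base_identifier is None:
        base = mint_identifier(repository)
        fact.base_identifier = base.base
    else:
        serial, _ = parse_identifier(fact.base_identifier)
        base = StableIdentifier(serial)

    existing = repository.releases.setdefault(base.serial, [])
    version = len(existing) + 1
    sbml_text = export_sbml(fact)
    bundle = evidence_bundle_of(fact)
    release = Release(
        base=base,
        version=version,
        content_sbml=sbml_text,
        evidence_bundle=bundle,
        content_hash=content_hash(sbml_text, bundle),
        release_notes=release_notes,
        released_by=actor,
        released_on=clock.now(),
        mi2cast_report=report,
        title=fact.title,
    )
    existing.append(release)
    repository._write_release(release)
    repository.audit_log.append(
        author=actor,
        verb="released",
        fact_key=fact.draft_uuid,
        target="/",
        comment=f"released {release.identifier}: {release_notes}",
    )
    return release


def get_fact(repository: Repository, identifier: str) -> Release:
    """Resolve ``bkcN`` (latest) or ``bkcNvM`` (exact version) to a release.

    The returned content is verified against the stored hash.
    """
    serial, version = parse_identifier(identifier)
    releases = repository.releases.get(serial)
    if not releases:
        raise NotFoundError(f"no released fact {identifier!r}")
    if version is None:
        release = releases[-1]
    elif 1 <= version <= len(releases):
        release = releases[version - 1]
    else:
        raise NotFoundError(
            f"version {version} of bkc{serial} does not exist (latest is {len(releases)})"
        )
    if content_hash(release.content_sbml, release.evidence_bundle) != release.content_hash:
        raise ValidationError(
            f"stored content of {release.identifier} does not match its hash"
        )
    return release


def version_history(repository: Repository, base: str) -> VersionHistory:
    """Complete ordered history of a released fact with notes and hashes."""
    serial, version = parse_identifier(base)
    if version is not None:
        raise FormatError("history takes a base identifier (bkcN), not a versioned one")
    releases = repository.releases.get(serial)
    if not releases:
        raise NotFoundError(f"no released fact {base!r}")
    return VersionHistory(
        base=StableIdentifier(serial),
        entries=[
            {
                "version": r.version,
                "released_on": r.released_on,
                "released_by": r.released_by,
                "notes": r.release_notes,
                "content_hash": r.content_hash,
            }
            for r in releases
        ],
    )


def delete_fact(repository: Repository, fact: Fact, actor: str) -> None:
    """Manager-only: remove the draft; released versions stay resolvable,
    flagged as withdrawn. The serial is tombstoned, never reused."""
    group = repository.group_of(fact)
    require_permission(group, actor, "delete_fact", fact.visibility)
    repository.drafts.pop(fact.draft_uuid, None)
    if fact.base_identifier is not None:
        serial, _ = parse_identifier(fact.base_identifier)
        repository.withdrawn.add(serial)
        for release in repository.releases.get(serial, []):
            release.withdrawn = True
            repository._write_release(release)
    repository.audit_log.append(
        author=actor,
        verb="deleted",
        fact_key=fact.draft_uuid,
        target="/",
        comment=f"deleted draft {fact.title!r}",
    )


def snapshot_fact(repository: Repository, identifier: str, group_ref: str | None = None) -> Fact:
    """Reconstruct an immutable Fact object from a release (for inspection)."""
    from .sbml import import_sbml

    release = get_fact(repository, identifier)
    fact = import_sbml(release.content_sbml, group_ref or "")
    fact.status = "released"
    fact.base_identifier = release.base.base
    return fact
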