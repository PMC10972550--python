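"""Users, groups, hierarchical per-group roles and advisory edit locks.

The four roles are totally ordered (reader < annotator < curator < manager)
and higher roles inherit every capability of lower ones:

=========  =========================================================
reader     view_fact
annotator  + annotate
curator    + edit_structure, release, vote
manager    + create_task, delete_fact, manage_group, mark_finished
=========  =========================================================

Non-members may view a fact only when its visibility is public. Voting on a
specific task is additionally open to that task's assignees regardless of
role (enforced in the review module). Edit locks are advisory: acquisition
always succeeds, but an unexpired lock held by someone else yields a
warning naming the holder.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

from . import clock
from .errors import CurationPermissionError, NotFoundError, ValidationError


class Role(enum.IntEnum):
    reader = 1
    annotator = 2
    curator = 3
    manager = 4


ACTIONS = (
    "view_fact",
    "annotate",
    "edit_structure",
    "release",
    "create_task",
    "vote",
    "delete_fact",
    "manage_group",
    "mark_finished",
)

# Minimal role required for each action; capabilities are inherited upward.
MINIMUM_ROLE: dict[str, Role] = {
    "view_fact": Role.reader,
    "annotate": Role.annotator,
    "edit_structure": Role.curator,
    "release": Role.curator,
    "vote": Role.curator,
    "create_task": Role.manager,
    "delete_fact": Role.manager,
    "manage_group": Role.manager,
    "mark_finished": Role.manager,
}


@dataclass
class User:
    user_id: str
    display_name: str = ""


@dataclass
class Group:
    group_id: str
    name: str
    visibility: str = "private"
    members: dict[str, Role] = field(default_factory=dict)

    def role_of(self, user_id: str) -> Optional[Role]:
        return self.members.get(user_id)

    def managers(self) -> list[str]:
        return sorted(u for u, r in self.members.items() if r == Role.manager)


@dataclass
class EditLock:
    fact_key: str
    holder: str
    acquired_on: datetime
    ttl: timedelta = timedelta(minutes=30)

    def expired(self, at: datetime) -> bool:
        return at >= self.acquired_on + self.ttl


@dataclass
class LockResult:
    granted: bool
    warning: Optional[str] = None  # holder user_id when contended


def create_group(
    name: str,
    visibility: str,
    founding_manager: str,
    *,
    group_id: str,
) -> Group:
    """Create a group whose sole member is the founder, as manager."""
    if not name or not name.strip():
        raise ValidationError("group name must be non-empty")
    if visibility not in ("private", "public"):
        raise ValidationError(f"unknown visibility {visibility!r}")
    return Group(
        group_id=group_id,
        name=name,
        visibility=visibility,
        members={founding_manager: Role.manager},
    )


def set_role(group: Group, actor: str, target_user: str, role: Role | str) -> Group:
    """Set (or add) a member's role; only managers may administer roles.

    Demoting or removing the last manager is refused: every group keeps at
    least one manager at all times.
    """
    role = Role[role] if isinstance(role, str) else Role(role)
    if group.role_of(actor) != Role.manager:
        raise CurationPermissionError(
            f"user {actor!r} is not a manager of group {group.group_id!r}"
        )
    if (
        group.role_of(target_user) == Role.manager
        and role != Role.manager
        and group.managers() == [target_user]
    ):
        raise ValidationError("cannot demote the last manager of a group")
    group.members[target_user] = role
    return group


def remove_member(group: Group, actor: str, target_user: str) -> Group:
    if group.role_of(actor) != Role.manager:
        raise CurationPermissionError(
            f"user {actor!r} is not a manager of group {group.group_id!r}"
        )
    if target_user not in group.members:
        raise NotFoundError(f"user {target_user!r} is not a member")
    if group.members[target_user] == Role.manager and group.managers() == [target_user]:
        raise ValidationError("cannot remove the last manager of a group")
    del group.members[target_user]
    return group


def check_permission(
    group: Group, user: str, action: str, fact_visibility: str = "private"
) -> bool:
    """Pure permission predicate over the documented role/action matrix."""
    if action not in ACTIONS:
        raise ValidationError(f"unknown action {action!r}")
    role = group.role_of(user)
    if role is None:
        return action == "view_fact" and fact_visibility == "public"
    return role >= MINIMUM_ROLE[action]


def require_permission(
    group: Group, user: str, action: str, fact_visibility: str = "private"
) -> None:
    if not check_permission(group, user, action, fact_visibility):
        raise CurationPermissionError(
            f"user {user!r} may not {action} in group {group.group_id!r}"
        )


def acquire_edit_lock(
    repository,
    fact_key: str,
    user: str,
    *,
    at: datetime | None = None,
    ttl: timedelta = timedelta(minutes=30),
) -> LockResult:
    """Advisory lock: always granted; warns when another unexpired holder exists."""
    at = at or clock.now()
    current = repository.locks.get(fact_key)
    if current is not None and not current.expired(at) and current.holder != user:
        repository.locks[fact_key] = EditLock(fact_key, user, at, ttl)
        return LockResult(granted=True, warning=current.holder)
    repository.locks[fact_key] = EditLock(fact_key, user, at, ttl)
    return LockResult(granted=True, warning=None)
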