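"""Review tasks: assignees, comments, votes and quorum-based completion.

A task completes only when (i) at least one manager has cast the
``mark_as_finished`` sign-off, (ii) the agreeing assignees — counting
manager sign-offs — reach the quorum fraction ``q`` of the assignee count
(``A >= ceil(q*n)``), and (iii) agrees strictly outnumber disagrees. The
rule is re-evaluated after every vote change, so completion is reversible
until the task is archived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

from . import clock
from .collaboration import Group, Role, check_permission
from .errors import CurationPermissionError, ValidationError

VOTE_VALUES = ("agree", "disagree", "mark_as_finished")


@dataclass
class Vote:
    user_id: str
    value: str
    cast_on: datetime


@dataclass
class QuorumPolicy:
    """Fraction of assignees that must agree (0 < q <= 1)."""

    q: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.q <= 1):
            raise ValidationError("quorum fraction must lie in (0, 1]")


@dataclass
class Task:
    task_id: str
    fact_key: str
    title: str
    description: str = ""
    assignees: set[str] = field(default_factory=set)
    status: str = "open"  # "open" | "completed"
    votes: dict[str, Vote] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)

    def log_event(self, kind: str, user: str, text: str) -> None:
        self.log.append(
            {"kind": kind, "user": user, "text": text, "timestamp": clock.now()}
        )


def create_task(
    fact,
    group: Group,
    actor: str,
    title: str,
    description: str,
    assignees,
    *,
    task_id: str,
) -> Task:
    """Managers assign a review task to group members."""
    if not check_permission(group, actor, "create_task"):
        raise CurationPermissionError(f"user {actor!r} may not create tasks")
    assignees = set(assignees)
    if not assignees:
        raise ValidationError("a task needs at least one assignee")
    outsiders = {u for u in assignees if group.role_of(u) is None}
    if outsiders:
        raise ValidationError(f"assignee(s) not in group: {sorted(outsiders)}")
    if not title or not title.strip():
        raise ValidationError("task title must be non-empty")
    task = Task(
        task_id=task_id,
        fact_key=fact.draft_uuid,
        title=title,
        description=description,
        assignees=assignees,
    )
    task.log_event("created", actor, f"task created for {sorted(assignees)}")
    return task


def may_vote(task: Task, group: Group, user: str) -> bool:
    """Assignees may always vote; otherwise curator-or-above."""
    return user in task.assignees or check_permission(group, user, "vote")


def cast_vote(
    task: Task,
    group: Group,
    user: str,
    value: str,
    policy: QuorumPolicy | None = None,
) -> Task:
    """Record (or replace) a user's vote and re-evaluate the quorum."""
    if value not in VOTE_VALUES:
        raise ValidationError(f"unknown vote value {value!r}")
    if not may_vote(task, group, user):
        raise CurationPermissionError(f"user {user!r} may not vote on task {task.task_id}")
    if value == "mark_as_finished" and group.role_of(user) != Role.manager:
        raise CurationPermissionError("only managers may cast 'mark as finished'")
    task.votes[user] = Vote(user_id=user, value=value, cast_on=clock.now())
    task.log_event("vote", user, value)
    evaluate_quorum(task, policy or QuorumPolicy(), group)
    return task


def evaluate_quorum(task: Task, policy: QuorumPolicy, group: Group) -> str:
    """Apply the completion rule and update ``task.status``.

    With n assignees: A = agree votes cast by assignees plus manager
    ``mark_as_finished`` votes (a manager-assignee signing off counts once);
    D = disagree votes by assignees. The task is completed iff a manager
    sign-off exists, A >= ceil(q*n) and A > D.
    """
    n = len(task.assignees)
    signed_off = any(
        v.value == "mark_as_finished" and group.role_of(u) == Role.manager
        for u, v in task.votes.items()
    )
    agrees = sum(
        1
        for u, v in task.votes.items()
        if (v.value == "agree" and u in task.assignees)
        or (v.value == "mark_as_finished" and group.role_of(u) == Role.manager)
    )
    disagrees = sum(
        1 for u, v in task.votes.items() if v.value == "disagree" and u in task.assignees
    )
    threshold = math.ceil(policy.q * n)
    completed = signed_off and agrees >= threshold and agrees > disagrees
    new_status = "completed" if completed else "open"
    if new_status != task.status:
        task.status = new_status
        task.log_event("status", "system", f"task {new_status}")
    return task.status


def add_comment(task: Task, group: Group, user: str, text: str,
                fact_visibility: str = "private") -> Task:
    """Append a comment; open to anyone who can view the fact."""
    if not text or not text.strip():
        raise ValidationError("comment must be non-empty")
    if not (user in task.assignees
            or check_permission(group, user, "view_fact", fact_visibility)):
        raise CurationPermissionError(f"user {user!r} may not view this fact")
    task.log_event("comment", user, text)
    return task
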