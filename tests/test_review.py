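"""Review tasks: vote permissions, quorum rule vs an exhaustive oracle."""

import itertools
import math

import pytest
from hypothesis import given, strategies as st

from factcurator import (
    CurationPermissionError,
    QuorumPolicy,
    ValidationError,
    add_comment,
    cast_vote,
    create_task,
    evaluate_quorum,
    generate_worked_example,
)
from factcurator.review import Task, Vote
from factcurator import clock
from factcurator.collaboration import Role


def make_task(assignees, task_id="t1"):
    return Task(task_id=task_id, fact_key="f1", title="review", assignees=set(assignees))


def set_votes(task, votes):
    task.votes = {
        u: Vote(user_id=u, value=v, cast_on=clock.now()) for u, v in votes.items()
    }


def quorum_oracle(assignees, manager_ids, votes, q):
    """Independent restatement of the completion rule, from first principles.

    n assignees; A = agree votes cast by assignees plus mark_as_finished
    votes cast by managers; D = disagree votes by assignees; completed iff
    some manager signed off AND A >= ceil(q*n) AND A > D.
    """
    n = len(assignees)
    sign_offs = [u for u, v in votes.items() if v == "mark_as_finished" and u in manager_ids]
    agree = sum(1 for u, v in votes.items() if v == "agree" and u in assignees)
    agree += sum(1 for u, v in votes.items() if v == "mark_as_finished" and u in manager_ids)
    disagree = sum(1 for u, v in votes.items() if v == "disagree" and u in assignees)
    return bool(sign_offs) and agree >= math.ceil(q * n) and agree > disagree


def make_group(assignees, manager_ids):
    from factcurator.collaboration import Group

    members = {u: Role.annotator for u in assignees}
    members.update({m: Role.manager for m in manager_ids})
    members.setdefault("alice", Role.manager)
    return Group(group_id="g1", name="team", members=members)


class TestQuorumOracle:
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    @pytest.mark.parametrize("q", [0.25, 0.5, 0.75, 1.0])
    def test_exhaustive_agreement_external_manager(self, n, q):
        assignees = [f"u{i}" for i in range(n)]
        group = make_group(assignees, {"mgr"})
        policy = QuorumPolicy(q=q)
        options = ["absent", "agree", "disagree"]
        for combo in itertools.product(options, repeat=n):
            for mgr_vote in ("absent", "agree", "disagree", "mark_as_finished"):
                votes = {u: v for u, v in zip(assignees, combo) if v != "absent"}
                if mgr_vote != "absent":
                    votes["mgr"] = mgr_vote
                task = make_task(assignees)
                set_votes(task, votes)
                status = evaluate_quorum(task, policy, group)
                expected = quorum_oracle(set(assignees), {"mgr", "alice"}, votes, q)
                assert (status == "completed") == expected, (combo, mgr_vote, q)

    @pytest.mark.parametrize("q", [0.5, 1.0])
    def test_exhaustive_agreement_manager_is_assignee(self, q):
        """A manager-assignee's sign-off must count once, not twice."""
        assignees = ["mgr", "u1", "u2"]
        group = make_group({"u1", "u2"}, {"mgr"})
        policy = QuorumPolicy(q=q)
        options = ["absent", "agree", "disagree", "mark_as_finished"]
        for combo in itertools.product(options[:3], repeat=2):
            for mgr_vote in options:
                votes = {u: v for u, v in zip(["u1", "u2"], combo) if v != "absent"}
                if mgr_vote != "absent":
                    votes["mgr"] = mgr_vote
                task = make_task(assignees)
                set_votes(task, votes)
                status = evaluate_quorum(task, policy, group)
                expected = quorum_oracle(set(assignees), {"mgr", "alice"}, votes, q)
                assert (status == "completed") == expected, (combo, mgr_vote, q)

    def test_spec_examples(self):
        group = make_group({"u2", "u3"}, {"mgr"})
        policy = QuorumPolicy(q=0.5)
        # n=3, manager sign-off + one agree -> A=2 >= 2, D=0 -> completed
        task = make_task({"mgr", "u2", "u3"})
        set_votes(task, {"mgr": "mark_as_finished", "u2": "agree"})
        assert evaluate_quorum(task, policy, group) == "completed"
        # all assignees agree but no sign-off -> open
        task = make_task({"u2", "u3"})
        set_votes(task, {"u2": "agree", "u3": "agree"})
        assert evaluate_quorum(task, policy, group) == "open"
        # n=3, only the manager sign-off -> A=1 < 2 -> open
        task = make_task({"mgr", "u2", "u3"})
        set_votes(task, {"mgr": "mark_as_finished"})
        assert evaluate_quorum(task, policy, group) == "open"


@given(st.lists(st.tuples(st.sampled_from(["u0", "u1", "u2", "mgr"]),
                          st.sampled_from(["agree", "disagree", "mark_as_finished"])),
                max_size=12))
def test_quorum_monotonicity(votes_seq):
    """Adding agree/sign-off votes never un-completes; adding disagree never
    completes an open task."""
    assignees = {"u0", "u1", "u2"}
    group = make_group(assignees, {"mgr"})
    policy = QuorumPolicy(q=0.5)
    task = make_task(assignees)
    prev = "open"
    for user, value in votes_seq:
        if value == "mark_as_finished" and user != "mgr":
            continue
        is_new_voter = user not in task.votes
        set_votes(task, {**{u: v.value for u, v in task.votes.items()}, user: value})
        status = evaluate_quorum(task, policy, group)
        if is_new_voter and value in ("agree", "mark_as_finished"):
            assert not (prev == "completed" and status == "open")
        if is_new_voter and value == "disagree":
            assert not (prev == "open" and status == "completed")
        prev = status


class TestTaskOperations:
    def test_manager_creates_task(self, repo, group, worked_example):
        t = create_task(worked_example, group, "alice", "check", "desc",
                        {"bob", "carol"}, task_id="t1")
        assert t.status == "open" and t.assignees == {"bob", "carol"}
        assert t.log[0]["kind"] == "created"

    def test_curator_cannot_create(self, group, worked_example):
        with pytest.raises(CurationPermissionError):
            create_task(worked_example, group, "bob", "x", "", {"carol"}, task_id="t1")

    def test_assignee_validation(self, group, worked_example):
        with pytest.raises(ValidationError):
            create_task(worked_example, group, "alice", "x", "", set(), task_id="t1")
        with pytest.raises(ValidationError):
            create_task(worked_example, group, "alice", "x", "", {"stranger"}, task_id="t1")

    def test_vote_eligibility_and_finish_permission(self, group):
        task = make_task({"carol"})
        cast_vote(task, group, "carol", "agree")  # annotator assignee may vote
        cast_vote(task, group, "bob", "agree")  # curator may vote
        with pytest.raises(CurationPermissionError):
            cast_vote(task, group, "dave", "agree")  # reader, not assigned
        with pytest.raises(CurationPermissionError):
            cast_vote(task, group, "bob", "mark_as_finished")  # curator, not manager

    def test_revote_replaces(self, group):
        task = make_task({"carol"})
        cast_vote(task, group, "carol", "agree")
        cast_vote(task, group, "carol", "disagree")
        assert len(task.votes) == 1
        assert task.votes["carol"].value == "disagree"

    def test_vote_triggers_completion_and_is_reversible(self, group):
        task = make_task({"carol"})
        cast_vote(task, group, "carol", "agree")
        cast_vote(task, group, "alice", "mark_as_finished")
        assert task.status == "completed"
        cast_vote(task, group, "carol", "disagree")
        assert task.status == "open"

    def test_comments(self, group):
        task = make_task({"carol"})
        add_comment(task, group, "dave", "looks fine")  # readers may comment
        with pytest.raises(ValidationError):
            add_comment(task, group, "dave", "  ")
        with pytest.raises(CurationPermissionError):
            add_comment(task, group, "stranger", "hi")
        kinds = [e["kind"] for e in task.log]
        assert kinds.count("comment") == 1
        assert all("timestamp" in e for e in task.log)
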