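import pytest
from hypothesis import HealthCheck, settings

from factcurator import clock

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(autouse=True)
def logical_clock():
    """Deterministic timestamps per test; restores the wall clock afterwards."""
    previous = clock.set_default_clock(clock.LogicalClock())
    yield
    clock.set_default_clock(previous)


@pytest.fixture
def repo():
    """In-memory repository with a group: alice=manager, bob=curator,
    carol=annotator, dave=reader."""
    from factcurator import Repository, create_group, set_role

    r = Repository()
    for u in ("alice", "bob", "carol", "dave"):
        r.add_user(u)
    g = create_group("team", "private", "alice", group_id=r.new_group_id())
    r.groups[g.group_id] = g
    set_role(g, "alice", "bob", "curator")
    set_role(g, "alice", "carol", "annotator")
    set_role(g, "alice", "dave", "reader")
    return r


@pytest.fixture
def group(repo):
    return repo.groups["g1"]


@pytest.fixture
def worked_example():
    from factcurator import generate_worked_example

    return generate_worked_example("g1")
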