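"""Fact construction, element removal cascades, validation and timestamps."""

import pytest
from hypothesis import given, strategies as st

from factcurator import (
    ConflictError,
    DanglingReferenceError,
    DependencyError,
    ImmutabilityError,
    NotFoundError,
    ValidationError,
    add_compartment,
    add_reaction,
    add_species,
    create_fact,
    fact_is_valid,
    remove_element,
    validate_fact,
)
from factcurator.sbml import export_sbml


def small_fact():
    f = create_fact("demo", "g1")
    add_compartment(f, "cytosol", "cytosol")
    add_species(f, "a", "A", "cytosol")
    add_species(f, "b", "B", "cytosol")
    add_species(f, "k", "K", "cytosol")
    add_reaction(f, "r1", ["a"], ["b"], ["k"], sbo_term="SBO:0000176")
    return f


class TestCreateFact:
    def test_empty_draft(self):
        f = create_fact("TP53-MDM2 binding", "g1", "private")
        assert f.status == "draft"
        assert (f.compartments, f.species, f.reactions) == ([], [], [])
        assert f.core.created_on <= f.core.updated_on

    def test_empty_title_rejected(self):
        with pytest.raises(ValidationError):
            create_fact("", "g1", "private")
        with pytest.raises(ValidationError):
            create_fact("   ", "g1")

    def test_draft_uuids_distinct(self):
        assert create_fact("x", "g1").draft_uuid != create_fact("x", "g1").draft_uuid


class TestAddElements:
    def test_compartment_then_duplicate(self):
        f = create_fact("x", "g1")
        add_compartment(f, "cytosol")
        assert len(f.compartments) == 1
        with pytest.raises(ConflictError):
            add_compartment(f, "cytosol")

    def test_mutation_refused_on_released_snapshot(self):
        f = small_fact()
        f.status = "released"
        f.base_identifier = "bkc1"
        with pytest.raises(ImmutabilityError):
            add_compartment(f, "nucleus")
        with pytest.raises(ImmutabilityError):
            remove_element(f, "a")

    def test_species_requires_compartment(self):
        f = create_fact("x", "g1")
        with pytest.raises(DanglingReferenceError):
            add_species(f, "tp53", "TP53", "nowhere")

    def test_species_insertion_order(self):
        f = create_fact("x", "g1")
        add_compartment(f, "c")
        for sid in ("s1", "s2", "s3"):
            add_species(f, sid, sid.upper(), "c")
        assert [s.core.local_id for s in f.species] == ["s1", "s2", "s3"]

    def test_reaction_roles_and_participants(self):
        f = small_fact()
        (r,) = f.reactions
        assert len(r.reactants) == len(r.products) == len(r.modifiers) == 1
        assert r.reactants[0].role == "reactant"
        assert r.modifiers[0].species_ref == "k"
        # every participant has its own annotatable core
        ids = {sr.core.local_id for sr in r.participants()}
        assert len(ids) == 3

    def test_reaction_errors(self):
        f = create_fact("x", "g1")
        add_compartment(f, "c")
        add_species(f, "a", "A", "c")
        with pytest.raises(DanglingReferenceError):
            add_reaction(f, "r1", ["a"], ["unknown_x"])
        with pytest.raises(ValidationError):
            add_reaction(f, "r1", [], [])
        with pytest.raises(ValidationError):
            add_reaction(f, "r1", [("a", -1)], ["a"])

    def test_invalid_sid_rejected(self):
        f = create_fact("x", "g1")
        with pytest.raises(ValidationError):
            add_compartment(f, "1bad")


class TestRemoveElement:
    def test_species_removal_cascades_to_references(self):
        # independent oracle: rebuild the same fact without K and compare exports
        f = small_fact()
        remove_element(f, "k")
        expected = create_fact("demo", "g1")
        add_compartment(expected, "cytosol", "cytosol")
        add_species(expected, "a", "A", "cytosol")
        add_species(expected, "b", "B", "cytosol")
        add_reaction(expected, "r1", ["a"], ["b"], sbo_term="SBO:0000176")
        assert f.reactions[0].modifiers == []
        assert export_sbml(f) == export_sbml(expected)

    def test_referenced_compartment_refused(self):
        f = small_fact()
        with pytest.raises(DependencyError):
            remove_element(f, "cytosol")

    def test_remove_then_readd_frees_id(self):
        f = small_fact()
        remove_element(f, "k")
        add_species(f, "k", "K2", "cytosol")
        assert f.get_species("k").core.display_name == "K2"

    def test_unknown_id(self):
        with pytest.raises(NotFoundError):
            remove_element(small_fact(), "ghost")

    def test_reaction_removal_drops_orphan_evidence(self):
        from factcurator import attach_sentence

        f = small_fact()
        attach_sentence(f, "only on r1", ["/reaction:r1"])
        remove_element(f, "r1")
        assert f.evidences == {}


class TestValidateFact:
    def test_well_formed_fact_clean(self):
        assert validate_fact(small_fact()) == []

    def test_dangling_compartment_ref_reported(self):
        f = small_fact()
        f.species[0].compartment_ref = "ghost"
        errors = [e for e in validate_fact(f) if e["severity"] == "error"]
        assert len(errors) == 1
        assert "ghost" in errors[0]["message"]

    def test_zero_reactions_flagged(self):
        f = create_fact("x", "g1")
        report = validate_fact(f)
        assert any("requires >=1 reaction" in e["message"] for e in report)
        assert not fact_is_valid(f)

    def test_isolated_species_is_warning_only(self):
        f = small_fact()
        add_species(f, "lonely", "L", "cytosol")
        report = validate_fact(f)
        assert any(e["severity"] == "warning" and "lonely" in e["path"] for e in report)
        assert fact_is_valid(f)

    def test_report_order_deterministic(self):
        f = small_fact()
        f.species[0].compartment_ref = "ghost"
        f.species[1].compartment_ref = "ghost2"
        assert validate_fact(f) == validate_fact(f)
        paths = [e["path"] for e in validate_fact(f)]
        assert paths == sorted(paths)


class TestTimestamps:
    def test_mutations_strictly_advance_updated_on(self):
        f = create_fact("x", "g1")
        stamps = [f.core.updated_on]
        add_compartment(f, "c")
        stamps.append(f.core.updated_on)
        add_species(f, "a", "A", "c")
        stamps.append(f.core.updated_on)
        add_reaction(f, "r1", ["a"], ["a"])
        stamps.append(f.core.updated_on)
        assert stamps == sorted(set(stamps))
        assert all(s2 > s1 for s1, s2 in zip(stamps, stamps[1:]))

    def test_element_created_on_stable_under_sibling_edits(self):
        f = small_fact()
        created = f.get_species("a").core.created_on
        add_species(f, "z", "Z", "cytosol")
        remove_element(f, "z")
        assert f.get_species("a").core.created_on == created


# -- property: referential closure under random op sequences ---------------

_op = st.sampled_from(["compartment", "species", "reaction", "remove"])


@given(st.lists(st.tuples(_op, st.integers(0, 5)), max_size=25))
def test_referential_closure_under_random_ops(ops):
    """Any op sequence that completes without error leaves no reference errors,
    and every element still exposes the shared annotatable surface."""
    f = create_fact("prop", "g1")
    counter = 0
    for kind, pick in ops:
        counter += 1
        try:
            if kind == "compartment":
                add_compartment(f, f"c{counter}")
            elif kind == "species":
                comps = [c.core.local_id for c in f.compartments]
                if comps:
                    add_species(f, f"s{counter}", "S", comps[pick % len(comps)])
            elif kind == "reaction":
                sps = [s.core.local_id for s in f.species]
                if sps:
                    add_reaction(f, f"r{counter}", [sps[pick % len(sps)]], [sps[0]])
            else:
                ids = f.all_local_ids()
                if ids:
                    remove_element(f, ids[pick % len(ids)])
        except (DependencyError, ConflictError, ValidationError, DanglingReferenceError):
            pass
    reference_errors = [
        e
        for e in validate_fact(f)
        if e["severity"] == "error" and "unknown" in e["message"]
    ]
    assert reference_errors == []
    for _, el in f.iter_elements():
        core = el.core
        assert hasattr(core, "identifier_annotations")
        assert hasattr(core, "notes")
        assert hasattr(core, "evidence_refs")
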