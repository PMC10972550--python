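"""Identifier annotations, evidence attachment, metadata resolution, MI2CAST."""

import pytest
from hypothesis import given, strategies as st

from factcurator import (
    AccessionError,
    ConflictError,
    DanglingReferenceError,
    FormatError,
    PublicationRef,
    RegistryError,
    ValidationError,
    annotate_element,
    attach_sentence,
    default_registry,
    resolve_publication_metadata,
    validate_mi2cast,
)
from factcurator.annotation import (
    BIOMODELS_QUALIFIERS,
    EmptyMetadataProvider,
    FixtureMetadataProvider,
    IdentifierAnnotation,
)
from factcurator.fixtures import (
    GeneratorConfig,
    generate_fact,
    generate_worked_example,
    mi2cast_rule_corpus,
)
from .test_core_model import small_fact


class TestRegistry:
    def test_bundled_snapshot_breadth(self):
        reg = default_registry()
        assert len(reg.entries) >= 20
        for prefix in ("uniprot", "chebi", "ncbigene", "hgnc", "go", "sbo",
                       "pubmed", "doi", "reactome"):
            assert prefix in reg

    def test_pattern_checks(self):
        reg = default_registry()
        reg.check("uniprot", "P04637")
        reg.check("chebi", "CHEBI:16236")
        with pytest.raises(AccessionError):
            reg.check("uniprot", "not-an-acc")
        with pytest.raises(RegistryError):
            reg.check("nonexistent_ns", "X1")

    def test_qualifier_vocabulary_closed(self):
        assert "bqbiol:is" in BIOMODELS_QUALIFIERS
        assert "bqmodel:isDescribedBy" in BIOMODELS_QUALIFIERS
        assert "bqbiol:madeUp" not in BIOMODELS_QUALIFIERS


class TestAnnotateElement:
    def test_uri_construction(self):
        f = small_fact()
        annotate_element(f, "/species:a", "bqbiol:is", "uniprot", "P04637")
        (ann,) = f.get_species("a").core.identifier_annotations
        assert ann.uri == "identifiers.org/uniprot:P04637"

    def test_bad_accession(self):
        with pytest.raises(AccessionError):
            annotate_element(small_fact(), "/species:a", "bqbiol:is", "uniprot", "nope")

    def test_duplicate_triple_rejected(self):
        f = small_fact()
        annotate_element(f, "/species:a", "bqbiol:is", "uniprot", "P04637")
        with pytest.raises(ConflictError):
            annotate_element(f, "/species:a", "bqbiol:is", "uniprot", "P04637")
        # a different qualifier with the same accession is a new annotation
        annotate_element(f, "/species:a", "bqbiol:isVersionOf", "uniprot", "P04637")
        assert len(f.get_species("a").core.identifier_annotations) == 2

    def test_unknown_qualifier_and_path(self):
        f = small_fact()
        with pytest.raises(ValidationError):
            annotate_element(f, "/species:a", "bqbiol:nonsense", "uniprot", "P04637")
        with pytest.raises(DanglingReferenceError):
            annotate_element(f, "/species:ghost", "bqbiol:is", "uniprot", "P04637")

    def test_annotation_on_species_reference_level(self):
        f = small_fact()
        sr = f.reactions[0].modifiers[0]
        path = f"/reaction:r1/modifier:{sr.core.local_id}"
        annotate_element(f, path, "bqbiol:is", "sbo", "SBO:0000019")
        assert sr.core.identifier_annotations


class TestAttachSentence:
    def test_multi_path_attachment_including_root(self):
        f = small_fact()
        _, ev_id = attach_sentence(
            f, "S", ["/reaction:r1", "/"], PublicationRef("pmid", "12345")
        )
        ev = f.evidences[ev_id]
        assert ev.attached_to == {"/reaction:r1", "/"}
        assert ev_id in f.core.evidence_refs
        assert ev_id in f.reactions[0].core.evidence_refs

    def test_identical_pair_merges(self):
        f = small_fact()
        prov = PublicationRef("pmid", "12345")
        _, e1 = attach_sentence(f, "S", ["/reaction:r1", "/"], prov)
        _, e2 = attach_sentence(f, "S", ["/species:a"], PublicationRef("pmid", "12345"))
        assert e1 == e2
        assert len(f.evidences) == 1
        assert f.evidences[e1].attached_to == {"/reaction:r1", "/", "/species:a"}

    def test_differing_provenance_stays_separate(self):
        f = small_fact()
        attach_sentence(f, "S", ["/"], PublicationRef("pmid", "12345"))
        attach_sentence(f, "S", ["/"], PublicationRef("pmid", "99999"))
        assert len(f.evidences) == 2

    def test_validation(self):
        f = small_fact()
        with pytest.raises(ValidationError):
            attach_sentence(f, "S", [])
        with pytest.raises(ValidationError):
            attach_sentence(f, "  ", ["/"])
        with pytest.raises(DanglingReferenceError):
            attach_sentence(f, "S", ["/species:ghost"])


@given(st.lists(st.sampled_from(["/", "/species:a", "/species:b", "/reaction:r1"]),
                min_size=1, max_size=4),
       st.integers(0, 3))
def test_evidence_bidirectionality_invariant(paths, n_extra):
    """p in e.attached_to iff e.evidence_id in element(p).evidence_refs."""
    f = small_fact()
    attach_sentence(f, "base sentence", paths)
    for i in range(n_extra):
        attach_sentence(f, f"extra {i}", [paths[i % len(paths)]])
    for ev in f.evidences.values():
        for path, el in f.iter_elements():
            assert (path in ev.attached_to) == (ev.evidence_id in el.core.evidence_refs)


class TestPublicationMetadata:
    def test_fixture_provider_hit(self):
        ref, resolved = resolve_publication_metadata(
            PublicationRef("pmid", "12345"), FixtureMetadataProvider()
        )
        assert resolved and ref.metadata["journal"].startswith("Synthetic")

    def test_empty_provider_miss_never_raises(self):
        ref, resolved = resolve_publication_metadata(
            PublicationRef("pmid", "12345"), EmptyMetadataProvider()
        )
        assert not resolved and ref.metadata is None

    @pytest.mark.parametrize(
        "id_type,value",
        [("pmcid", "12345"), ("pmid", "12x45"), ("doi", "zz.1000/x"), ("isbn", "1")],
    )
    def test_malformed_ids_raise_format_error(self, id_type, value):
        with pytest.raises(FormatError):
            PublicationRef(id_type, value)


class TestMi2cast:
    def test_worked_example_passes_mandatory_rules(self):
        report = validate_mi2cast(generate_worked_example())
        (r,) = report["reactions"]
        assert r["rule1_entities"] and r["rule2_effect"] and r["rule3_evidence"]
        assert report["overall"]

    @pytest.mark.parametrize("failing_rule", [1, 2, 3, 4])
    def test_each_rule_toggles_independently(self, failing_rule):
        corpus = mi2cast_rule_corpus()
        report = validate_mi2cast(corpus[f"fail_rule{failing_rule}"])
        (r,) = report["reactions"]
        flags = {
            1: r["rule1_entities"],
            2: r["rule2_effect"],
            3: r["rule3_evidence"],
            4: r["rule4_context"],
        }
        for rule, value in flags.items():
            assert value == (rule != failing_rule), (failing_rule, flags)
        assert r["overall"] == (failing_rule == 4)

    def test_fully_compliant_fact(self):
        report = validate_mi2cast(mi2cast_rule_corpus()["pass_all"])
        (r,) = report["reactions"]
        assert all(
            r[k] for k in ("rule1_entities", "rule2_effect", "rule3_evidence", "rule4_context")
        )

    def test_deterministic_and_side_effect_free(self):
        f = generate_fact(GeneratorConfig(seed=7))
        from factcurator.sbml import export_sbml

        before = export_sbml(f)
        r1 = validate_mi2cast(f)
        r2 = validate_mi2cast(f)
        assert r1 == r2
        assert export_sbml(f) == before

    def test_fact_with_no_evidence_fails_rule3(self):
        f = small_fact()
        f.reactions[0].core.sbo_term = "SBO:0000176"
        (r,) = validate_mi2cast(f)["reactions"]
        assert not r["rule3_evidence"] and not r["overall"]
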