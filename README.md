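# factcurator

A headless curation engine for **systems-biology facts**: minimal, reusable
units of curated knowledge — molecular species enclosed in compartments and
connected by one or more reactions (with SBML's reactant / product /
modifier semantics) — together with the annotations and literature evidence
that make them citable building blocks for pathway diagrams and
computational models.

It is written for biocurators and tool builders who need the *knowledge*
side of model curation decoupled from diagram layout: structured facts,
database cross-references, sentence-level provenance, collaborative review
and stable versioned identifiers, all serializable to standard SBML
Level 3.

## What the engine does

- **SBML-aligned data model.** Every element of a fact — the fact root,
  compartments, species, reactions, and each per-participant species
  reference — embeds one shared annotatable core (name, SBO term,
  identifier annotations, notes, evidence references, timestamps), so
  annotation is possible at every level of the hierarchy.
- **Identifier annotation.** Cross-references pair a BioModels qualifier
  (`bqbiol:is`, `bqmodel:isDescribedBy`, ...) with an Identifiers.org
  namespace prefix and an accession validated against that namespace's
  pattern (a versioned registry snapshot ships with the package). Each
  annotation yields a canonical URI `identifiers.org/<prefix>:<accession>`.
- **Evidence sentences.** Literature sentences with optional publication
  provenance (PMID, PMCID or DOI) attach to one or many element paths,
  including the fact root; identical (sentence, provenance) pairs merge.
- **SBML Level 3 I/O.** Facts export to canonical SBML L3V2 with MIRIAM RDF
  annotations; the importer accepts L3V1/L3V2, legacy `urn:miriam` URNs,
  species without compartments, and unknown annotation payloads (preserved
  verbatim). `import(export(f))` is semantically the identity.
- **Stable identifiers and releases.** A fact releases under `bkcN`;
  subsequent releases become `bkcNv2`, `bkcNv3`, ... Each release is an
  immutable SHA-256–hashed snapshot with release notes; the base identifier
  always resolves to the latest version, and serials are never reused.
- **Collaboration and review.** Groups with four totally ordered roles
  (reader < annotator < curator < manager), an explicit permission matrix,
  advisory edit locks, and review tasks completed by a vote quorum that
  always requires a manager's "mark as finished" sign-off:
  completed ⇔ sign-off ∧ A ≥ ⌈q·n⌉ ∧ A > D, where n is the assignee count,
  A the agreeing assignees (manager sign-offs included) and D the
  disagreeing ones.
- **Compliance checking.** A per-reaction report against the four
  minimum-information rules for causal molecular interaction statements
  (MI2CAST): source/target entities, interaction effect (SBO), evidence
  provenance, and (advisory) biological context.
- **Audit log.** Every successful mutation appends exactly one authored,
  timestamped action record, filterable per element subtree and linkable to
  review tasks.
- **Basket workflow.** Evidence-first curation: collect sentences (bulk TSV
  import supported), then "check out" selected items into a new draft fact.

## Worked example

```python
import factcurator as fc

repo = fc.Repository()                      # in-memory; pass a path to persist
repo.add_user("alice"); repo.add_user("bob")
group = fc.create_group("p53-team", "private", "alice", group_id=repo.new_group_id())
repo.groups[group.group_id] = group
fc.set_role(group, "alice", "bob", "curator")

fact = fc.generate_worked_example(group.group_id)   # MDM2-mediated TP53 ubiquitination
repo.drafts[fact.draft_uuid] = fact
print(fc.validate_mi2cast(fact)["reactions"][0])

release = fc.release_fact(repo, fact, "initial curated version", "bob")
print(release.identifier, release.content_hash[:12])

fc.add_species(fact, "p21", "CDKN1A", "cytosol")     # the draft stays editable
fc.add_reaction(fact, "r2", ["p21"], ["tp53"])
r2 = fc.release_fact(repo, fact, "added the CDKN1A feedback", "bob")
print(r2.identifier, r2.content_hash[:12])
print("latest via base id:", fc.get_fact(repo, "bkc1").version)
```

prints

```
{'reaction': 'r1', 'rule1_entities': True, 'rule2_effect': True, 'rule3_evidence': True, 'rule4_context': False, 'overall': True}
bkc1v1 2d76b0c10ba1
bkc1v2 85acc8c3d37c
latest via base id: 2
```

The compliance report shows the demo reaction satisfies the three mandatory
rules (entities, SBO-typed effect, provenanced evidence); context
annotation is only a recommendation. The two releases are immutable
snapshots with distinct content hashes; version 1 remains retrievable as
`bkc1v1` even though the draft has moved on.

The same workflows are available from the shell via the `factcur` command
(`factcur init`, `fact new/add-species/annotate/evidence`, `sbml
import/export`, `release`, `get bkc1v2`, `history`, `basket`, `task`,
`log show`); errors carry stable prefixes (`E_VALIDATION`, `E_PERMISSION`,
`E_NOTFOUND`, `E_FORMAT`).

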