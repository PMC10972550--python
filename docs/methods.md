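# Methods

This note documents the data model, the behavioural rules the engine
implements, the defaults and numerical choices, what the synthetic
generators do and do not emulate, and known limitations.

## The fact model

A *fact* is a collection of elements connected by at least one interaction:
compartments, species (each enclosed in a compartment) and reactions whose
participants are per-slot species references with SBML roles (reactant,
product, modifier). Every element type embeds exactly one shared
*annotatable core* — local id, display name, optional SBO term, identifier
annotations, notes, evidence references, `created_on`/`updated_on`
timestamps — mirroring SBML's SBase inheritance, so annotation is uniform
at every level, including individual reaction participants and the fact
root itself.

Elements are addressed by slash paths (`/`, `/species:tp53`,
`/reaction:r1/modifier:r1_sr3`). Local ids are SBML SIds, unique across the
whole fact; species-reference ids are generated as `<reaction>_sr<N>`.
Stoichiometry defaults to 1, must be positive, and is ignored for
modifiers, following SBML core semantics.

Structural editing is restricted to drafts. Removal cascades
conservatively: deleting a species removes its species references from all
reactions; deleting a compartment that still encloses species is refused.
An evidence whose last attachment path disappears in such a cascade is
dropped from the fact's evidence table — silently re-homing it to the root
would fabricate an attachment the curator never made. Validation returns a
deterministic report ordered by element path; error-severity entries
(dangling references, duplicate ids, reactions with no participants, zero
reactions) gate export and release, while isolated species produce
warnings only, so an exploratory draft can still be released when a curator
deliberately keeps unreacted building blocks.

Timestamps come from a strictly monotonic clock (wall time with
microsecond tie-breaking); every successful mutation strictly advances the
touched element's `updated_on` and the root's, and never alters
`created_on`.

## Annotation and evidence

Identifier annotations are (qualifier, namespace prefix, accession)
triples. The qualifier vocabulary is the closed BioModels list
(`bqbiol:*`, `bqmodel:*`), frozen in a data file. Namespace prefixes and
accession patterns come from a versioned snapshot of the Identifiers.org
registry shipped as a TSV (33 common prefixes; any file with the same
three-column layout can be loaded instead). Accessions are validated
against the namespace pattern at annotation time; duplicates of the exact
triple on one element are rejected. The canonical URI is derived, never
stored: `identifiers.org/<prefix>:<accession>`.

Sentence evidences carry optional publication provenance (`pmid` digits,
`pmcid` matching `PMC\d+`, `doi` starting `10.`). Attaching an identical
(sentence, provenance) pair again merges attachment paths instead of
duplicating the evidence; differing provenance keeps sentences separate.
Evidence attachment is bidirectional by construction: a path is listed in
the evidence iff the element at that path references the evidence id.

Publication metadata resolution is a pluggable provider contract
(`lookup(id_type, id_value) -> metadata | None`); the default provider is
an offline table of clearly synthetic records. Lookup failures set a flag
and never raise; only syntactically malformed identifiers are errors.

## MI2CAST compliance

The checker reports, per reaction: **rule 1** — at least one source
(reactant or modifier) and one target (product); **rule 2** — the reaction
carries an SBO term typing the effect (reaction-level typing was chosen
over modifier-level, as the effect describes the interaction, not a
participant); **rule 3** — the reaction, one of its participants, or the
fact root has at least one evidence with provenance; **rule 4** (advisory)
— an enclosing compartment of the participants is annotated or every
participating species carries an identifier annotation. Overall compliance
requires rules 1–3 only. Releases attach the report; a configurable strict
mode additionally blocks release when rules 1–3 fail (default: warn only,
since compliance of stored content and gating of publication are separate
policies).

## SBML serialization

Export writes SBML Level 3 Version 2 core with MIRIAM RDF annotations (one
`rdf:Description` per element metaid, one `rdf:Bag` per qualifier,
resources as `https://identifiers.org/<prefix>:<accession>`); metaids are
`meta_<local_id>`. Evidence sentences are embedded in each attached
element's `annotation` under a dedicated project namespace
(`https://factcurator.dev/ns/evidence/1`) — not in `notes` — so human notes
stay free text and the MIRIAM block remains readable by standard tools.
Export is canonical: a pure function of curated content (timestamps, group
membership and audit data are never serialized), with fixed attribute
order and siblings sorted (annotations by qualifier/prefix/accession,
evidences by id), so identical facts give byte-identical documents. This
canonical form is also the basis of release hashing and of semantic
equality in tests.

Import accepts L3V1 and L3V2, raises a dedicated unsupported-level error
for Levels 1/2, normalizes legacy `urn:miriam:` URNs (including
percent-encoded accessions) to the identifiers.org form, auto-creates a
`default` compartment for species without one, and preserves any
unrecognized annotation content verbatim in opaque notes (re-emitted on
export) with a warning — imports never fail on unknown payloads.

## Versioning and the repository store

Stable identifiers are `bkc<serial>`; serials strictly increase per
repository and are never reused, even after deletion (tombstoning keeps
withdrawn releases resolvable, flagged as withdrawn). Versions of one fact
are consecutive integers from 1; `bkcN` resolves to the latest release,
`bkcNvM` to exactly version M. History is linear — the engine models
sequential releases, not branches. The release content hash is SHA-256
over the canonical SBML text concatenated with a canonical sorted JSON
evidence bundle, and is re-verified on every retrieval. Releasing never
locks the draft: released versions are snapshots, and only snapshot
objects reconstructed from a release refuse mutation.

The store is a plain-text directory tree (JSON state and drafts, one
`content.sbml` + `record.json` per release version, an append-only TSV
audit journal), chosen over an embedded database for transparency and
diff-ability. Repositories can also run fully in memory.

## Collaboration, review, audit

Roles are hierarchical: reader ⊂ annotator (+annotate) ⊂ curator
(+edit_structure, release, vote) ⊂ manager (+create_task, delete_fact,
manage_group, mark_finished). Capability sets are stated disjointly in
curation practice, but the grant list "read, annotation, curation or
management" implies inheritance, and the hierarchy keeps the matrix
monotone. Non-members may view public facts only. Every group keeps at
least one manager at all times. Edit locks are advisory with a 30-minute
TTL: acquisition always succeeds, and contention only produces a warning
naming the holder.

Task completion: with n assignees and quorum fraction q (repository
default 0.5), A = agree votes by assignees plus manager `mark_as_finished`
votes (a manager-assignee signing off counts once), D = disagree votes by
assignees; the task completes iff a manager sign-off exists, A ≥ ⌈q·n⌉ and
A > D. The quorum threshold is deliberately configurable because only "a
certain positive quorum" is required by the workflow being modelled; the
A > D term encodes annotator agreement, the sign-off term the manager's
final word. Votes replace a user's prior vote; the rule is re-evaluated on
every change, and completion is reversible until archival. Eligibility:
task assignees always vote; otherwise curator-or-above; `mark_as_finished`
is manager-only.

Audit: exactly one record per successful mutation (failed operations emit
nothing — clean history); imports emit one `imported` record for the whole
fact rather than one per element, avoiding log explosion on large
documents. Records are append-only; task links are journalled as extra
lines so the on-disk log only ever grows.

## Basket workflow

The TSV dialect is UTF-8, tab-delimited, header required with at least a
`sentence` column, no quoting, tabs/newlines forbidden inside fields.
Provenance is taken from the first present id column in priority order
pmid > pmcid > doi. Malformed rows (empty sentence, malformed identifier,
duplicate of an existing item) are rejected individually with line numbers;
the import never partially corrupts the basket. Checkout attaches every
selected sentence to the new fact's root — redistribution to specific
elements is a subsequent annotation step — and entity hints pre-create
species (in an auto-created `default` compartment) with `bqbiol:is`
annotations.

## Synthetic generators and what they show

The fact generator draws topology (1–2 compartments, 2–6 species, 1–3
reactions by default), `bqbiol:is` annotations (probability 0.6 per
element) and provenanced evidence (probability 0.7 per reaction) from a
seeded RNG; accessions are pattern-conforming strings, not real database
records, and every species is wired into at least one reaction so
generated facts validate cleanly. These defaults emulate the size of a
typical hand-curated interaction unit (a few species, one or a few
reactions). The generators do **not** emulate realistic pathway topology
statistics, real accession semantics, or adversarial SBML (beyond the four
dialect variants: identifiers.org URIs, legacy URNs, missing compartments,
unknown namespaces). Passing tests therefore demonstrate contract
correctness — round-trip fidelity, immutability, permission and quorum
semantics — not robustness against arbitrary wild SBML.

Problem sizes used by the verification script (200 round-trip facts, 100
edit/release interleavings, exhaustive quorum enumeration up to 4
assignees, 10 audit sequences × 40 operations, 10 TSV files × 12–14 rows)
were chosen as the package's own standard corpus: large enough to exercise
every code path and rule combination, small enough to run in seconds.

## Numerical and degenerate-input choices

- Stoichiometries serialize as integers when integral, `repr` otherwise.
- Validation reports sort by (path, severity, message); ties are stable.
- Evidence ids are `ev<N>` with numeric-aware ordering in exports.
- Quorum fraction q must lie in (0, 1]; ⌈q·n⌉ with n = 0 assignees cannot
  occur (tasks require at least one assignee).
- Empty titles, sentences, release notes and comments are rejected as
  whitespace-insensitive validation errors.
- Identifier parsing is strict (`bkc\d+(v\d+)?`); anything else is a
  format error, distinguishing malformed ids from missing ones.

## Known limitations

- No complexes or multistate species; reactions reference plain species.
- No kinetic laws, rules, events, units or layout in SBML I/O — none are
  part of a fact.
- Version history is linear; no branching or merging of releases.
- The permission model is a single trust domain (the CLI's `--as USER` is
  not authentication).
- The bundled registry snapshot is a small offline subset; syncing a full
  registry is out of scope, though any snapshot file can be substituted.
- Inter-annotator agreement is by open voting; the workflow is not blind.
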