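"""Deterministic synthetic fixtures: facts, foreign SBML documents, TSV files.

Everything is generated from an explicit seed — identical config and seed
always yield identical structures — so every module is testable offline.
Biological names are decorative; accessions are drawn to match the bundled
registry snapshot's patterns but are not claims about real database
records.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable

from .annotation import PublicationRef, annotate_element, attach_sentence, default_registry
from .core import (
    Fact,
    add_compartment,
    add_reaction,
    add_species,
    create_fact,
    fact_is_valid,
)
from .errors import ValidationError

_SPECIES_NAMES = (
    "TP53", "MDM2", "AKT1", "CDKN1A", "EGFR", "MAPK1", "STAT3", "JUN",
    "RELA", "CTNNB1", "GSK3B", "CASP3", "BCL2", "MYC", "HIF1A", "VEGFA",
)
_COMPARTMENT_NAMES = ("cytosol", "nucleus", "plasma_membrane", "mitochondrion")
_SBO_TERMS = (
    "SBO:0000176",  # biochemical reaction
    "SBO:0000216",  # ubiquitination
    "SBO:0000217",  # glycosylation
    "SBO:0000330",  # dephosphorylation
    "SBO:0000177",  # non-covalent binding
)
_SENTENCES = (
    "{a} directly binds {b} in resting cells.",
    "Phosphorylation of {a} by {b} promotes its degradation.",
    "{a} acts upstream of {b} in the stress response.",
    "Loss of {a} stabilizes {b} under hypoxia.",
    "{a} forms a transient complex with {b} upon stimulation.",
)

# Per-prefix accession makers, consistent with the bundled snapshot patterns.
_ACCESSION_MAKERS: dict[str, Callable[[random.Random], str]] = {
    "uniprot": lambda rng: f"P{rng.randint(10000, 99999)}",
    "chebi": lambda rng: f"CHEBI:{rng.randint(1000, 99999)}",
    "ncbigene": lambda rng: str(rng.randint(1, 99999)),
    "hgnc": lambda rng: str(rng.randint(1, 39999)),
    "go": lambda rng: f"GO:{rng.randint(0, 9999999):07d}",
    "pubmed": lambda rng: str(rng.randint(1000000, 39999999)),
    "mesh": lambda rng: f"D{rng.randint(100000, 999999)}",
    "interpro": lambda rng: f"IPR{rng.randint(0, 999999):06d}",
}


@dataclass
class GeneratorConfig:
    """Study conditions for the random fact generator."""

    seed: int = 0
    n_species: tuple[int, int] = (2, 6)
    n_reactions: tuple[int, int] = (1, 3)
    n_compartments: tuple[int, int] = (1, 2)
    annotation_density: float = 0.6
    evidence_density: float = 0.7
    prefixes: tuple[str, ...] = ("uniprot", "chebi", "ncbigene", "hgnc", "go")

    def __post_init__(self) -> None:
        for lo, hi, what, minimum in (
            (*self.n_species, "n_species", 1),
            (*self.n_reactions, "n_reactions", 1),
            (*self.n_compartments, "n_compartments", 1),
        ):
            if lo > hi or lo < minimum:
                raise ValidationError(f"degenerate range for {what}: [{lo}, {hi}]")
        for p in (self.annotation_density, self.evidence_density):
            if not (0 <= p <= 1):
                raise ValidationError("densities must lie in [0, 1]")
        unknown = [p for p in self.prefixes if p not in _ACCESSION_MAKERS]
        if unknown:
            raise ValidationError(f"no accession maker for prefixes {unknown}")


def generate_fact(config: GeneratorConfig, group_ref: str = "g1") -> Fact:
    """Seed-deterministic, structurally valid fact with annotations and evidence."""
    rng = random.Random(config.seed)
    registry = default_registry()
    n_comp = rng.randint(*config.n_compartments)
    n_spec = rng.randint(*config.n_species)
    n_rxn = rng.randint(*config.n_reactions)

    fact = create_fact(f"Synthetic fact (seed {config.seed})", group_ref)
    comp_ids = []
    for i in range(n_comp):
        cid = f"c{i + 1}"
        add_compartment(fact, cid, _COMPARTMENT_NAMES[i % len(_COMPARTMENT_NAMES)])
        comp_ids.append(cid)
    species_ids = []
    names = list(_SPECIES_NAMES)
    rng.shuffle(names)
    for i in range(n_spec):
        sid = f"s{i + 1}"
        add_species(fact, sid, names[i % len(names)], rng.choice(comp_ids))
        species_ids.append(sid)

    # participant sets: every species ends up in at least one reaction
    unused = set(species_ids)
    plans = []
    for i in range(n_rxn):
        k_r = rng.randint(1, min(2, n_spec))
        k_p = rng.randint(1, min(2, n_spec))
        reactants = rng.sample(species_ids, k_r)
        products = rng.sample(species_ids, k_p)
        modifiers = rng.sample(species_ids, 1) if rng.random() < 0.4 and n_spec > 2 else []
        plans.append([reactants, products, modifiers])
        unused -= set(reactants) | set(products) | set(modifiers)
    for sid in sorted(unused):
        plans[rng.randrange(len(plans))][0].append(sid)
    for i, (reactants, products, modifiers) in enumerate(plans):
        add_reaction(
            fact,
            f"r{i + 1}",
            [(s, rng.choice((1, 1, 2))) for s in reactants],
            products,
            modifiers,
            sbo_term=rng.choice(_SBO_TERMS) if rng.random() < 0.8 else None,
            reversible=rng.random() < 0.2,
        )

    used_annotations: set[tuple[str, str, str]] = set()
    for path in [f"/species:{s}" for s in species_ids] + [f"/compartment:{c}" for c in comp_ids]:
        if rng.random() < config.annotation_density:
            prefix = rng.choice(config.prefixes)
            accession = _ACCESSION_MAKERS[prefix](rng)
            key = (path, prefix, accession)
            if key in used_annotations:
                continue
            used_annotations.add(key)
            annotate_element(fact, path, "bqbiol:is", prefix, accession, registry)

    for i in range(n_rxn):
        if rng.random() < config.evidence_density:
            a, b = rng.sample(names[: max(2, n_spec)], 2)
            sentence = rng.choice(_SENTENCES).format(a=a, b=b)
            paths = [f"/reaction:r{i + 1}"]
            if rng.random() < 0.5:
                paths.append("/")
            provenance = PublicationRef("pmid", str(rng.randint(1000000, 39999999)))
            attach_sentence(fact, sentence, paths, provenance, "external")

    assert fact_is_valid(fact)
    return fact


def generate_worked_example(group_ref: str = "g1") -> Fact:
    """The canonical demo fact: MDM2-mediated ubiquitination of TP53.

    One cytosolic reaction TP53 -> TP53_ub with modifier MDM2, typed
    SBO:0000216 (ubiquitination), species annotated with their UniProt
    accessions, and one root evidence sentence with a synthetic PMID.
    Passes the mandatory MI2CAST rules 1-3.
    """
    fact = create_fact("MDM2-mediated ubiquitination of TP53", group_ref)
    add_compartment(fact, "cytosol", "cytosol")
    add_species(fact, "mdm2", "MDM2", "cytosol")
    add_species(fact, "tp53", "TP53", "cytosol")
    add_species(fact, "tp53_ub", "TP53_ub", "cytosol")
    add_reaction(
        fact, "r1", ["tp53"], ["tp53_ub"], ["mdm2"], sbo_term="SBO:0000216"
    )
    annotate_element(fact, "/species:tp53", "bqbiol:is", "uniprot", "P04637")
    annotate_element(fact, "/species:mdm2", "bqbiol:is", "uniprot", "Q00987")
    attach_sentence(
        fact,
        "MDM2 promotes the ubiquitination and degradation of TP53.",
        ["/"],
        PublicationRef("pmid", "10000001"),
        "external",
    )
    return fact


def mi2cast_rule_corpus(group_ref: str = "g1") -> dict[str, Fact]:
    """Facts that each fail exactly one MI2CAST rule (plus a fully passing one).

    Keys: "fail_rule1" .. "fail_rule4", "pass_all". Used to show that the
    compliance checker's four flags toggle independently.
    """

    def base(title: str, with_product: bool = True) -> Fact:
        f = create_fact(title, group_ref)
        add_compartment(f, "cytosol", "cytosol")
        add_species(f, "a", "A", "cytosol")
        add_species(f, "b", "B", "cytosol")
        if with_product:
            add_reaction(f, "r1", ["a"], ["b"], sbo_term="SBO:0000176")
        else:
            add_reaction(f, "r1", ["a", "b"], [], sbo_term="SBO:0000176")
        return f

    def annotate_context(f: Fact) -> Fact:
        annotate_element(f, "/species:a", "bqbiol:is", "uniprot", "P10000")
        annotate_element(f, "/species:b", "bqbiol:is", "uniprot", "P10001")
        return f

    def evidence(f: Fact, provenanced: bool = True) -> Fact:
        attach_sentence(
            f,
            "A converts to B in vitro.",
            ["/"],
            PublicationRef("pmid", "10000002") if provenanced else None,
            "external",
        )
        return f

    corpus: dict[str, Fact] = {}

    corpus["fail_rule1"] = evidence(annotate_context(base("No target entity", with_product=False)))
    corpus["fail_rule2"] = evidence(annotate_context(base("No effect term")))
    corpus["fail_rule2"].reactions[0].core.sbo_term = None
    corpus["fail_rule3"] = annotate_context(base("No provenance"))
    evidence(corpus["fail_rule3"], provenanced=False)
    corpus["fail_rule4"] = evidence(base("No context annotation"))
    corpus["pass_all"] = evidence(annotate_context(base("Fully compliant")))
    return corpus


def generate_foreign_sbml(config: GeneratorConfig, variant: str = "uri") -> str:
    """Third-party-style SBML L3 text exercising importer tolerance.

    Variants: "uri" (identifiers.org HTTPS resources), "urn" (legacy
    urn:miriam URNs, Level 3 Version 1 namespace), "no_compartment"
    (species without a compartment attribute), "unknown_ns" (annotation
    content in an unregistered namespace and an unknown registry prefix).
    """
    if variant not in ("uri", "urn", "no_compartment", "unknown_ns"):
        raise ValidationError(f"unknown foreign-SBML variant {variant!r}")
    rng = random.Random(config.seed * 131 + ("uri", "urn", "no_compartment", "unknown_ns").index(variant))
    n_spec = rng.randint(*config.n_species)
    ns = (
        "http://www.sbml.org/sbml/level3/version1/core"
        if variant == "urn"
        else "http://www.sbml.org/sbml/level3/version2/core"
    )
    version = "1" if variant == "urn" else "2"

    species_lines = []
    for i in range(n_spec):
        sid = f"x{i + 1}"
        comp = "" if variant == "no_compartment" else ' compartment="cell"'
        acc = f"P{rng.randint(10000, 99999)}"
        if variant == "urn":
            resource = f"urn:miriam:uniprot:{acc}"
        elif variant == "unknown_ns" and i == 0:
            resource = f"https://identifiers.org/notaregistry:{acc}"
        else:
            resource = f"https://identifiers.org/uniprot:{acc}"
        extra = ""
        if variant == "unknown_ns" and i == 0:
            extra = '<custom:tag xmlns:custom="https://example.org/custom">payload</custom:tag>'
        species_lines.append(
            f'<species id="{sid}" name="{_SPECIES_NAMES[i % len(_SPECIES_NAMES)]}"{comp} '
            f'hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" '
            f'metaid="meta_{sid}">'
            f"<annotation>"
            f'<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#" '
            f'xmlns:bqbiol="http://biomodels.net/biology-qualifiers/">'
            f'<rdf:Description rdf:about="#meta_{sid}"><bqbiol:is><rdf:Bag>'
            f'<rdf:li rdf:resource="{resource}"/>'
            f"</rdf:Bag></bqbiol:is></rdf:Description></rdf:RDF>"
            f"{extra}"
            f"</annotation></species>"
        )

    reactants = f'<speciesReference species="x1" stoichiometry="1" constant="true"/>'
    products = (
        f'<speciesReference species="x{n_spec}" stoichiometry="1" constant="true"/>'
        if n_spec > 1
        else f'<speciesReference species="x1" stoichiometry="1" constant="true"/>'
    )
    compartment = (
        ""
        if variant == "no_compartment"
        else '<listOfCompartments><compartment id="cell" constant="true"/></listOfCompartments>'
    )
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<sbml xmlns="{ns}" level="3" version="{version}">'
        f'<model id="foreign_model" name="Foreign model (seed {config.seed})">'
        f"{compartment}"
        f"<listOfSpecies>{''.join(species_lines)}</listOfSpecies>"
        f'<listOfReactions><reaction id="j1" reversible="false">'
        f"<listOfReactants>{reactants}</listOfReactants>"
        f"<listOfProducts>{products}</listOfProducts>"
        f"</reaction></listOfReactions>"
        f"</model></sbml>"
    )


def generate_evidence_tsv(seed: int, n_rows: int = 8, *, bad_rows: bool = True) -> str:
    """TSV evidence file for basket import tests; optionally includes rows
    that must be rejected (empty sentence, malformed PMID)."""
    rng = random.Random(seed)
    lines = ["sentence\tpmid\tpmcid\tdoi\tsource"]
    for i in range(n_rows):
        a, b = rng.sample(_SPECIES_NAMES, 2)
        sentence = rng.choice(_SENTENCES).format(a=a, b=b) + f" (row {i + 1})"
        kind = rng.choice(("pmid", "pmcid", "doi", ""))
        pmid = str(rng.randint(1000000, 9999999)) if kind == "pmid" else ""
        pmcid = f"PMC{rng.randint(100000, 999999)}" if kind == "pmcid" else ""
        doi = f"10.1000/synth.{rng.randint(1000, 9999)}" if kind == "doi" else ""
        lines.append(f"{sentence}\t{pmid}\t{pmcid}\t{doi}\texternal")
    if bad_rows:
        lines.append("\t1234567\t\t\texternal")  # empty sentence
        lines.append("A malformed provenance row.\tnot_digits\t\t\texternal")
    return "\n".join(lines) + "\n"
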