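prefix	pattern	name
uniprot	^([OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2})$	UniProt Knowledgebase
chebi	^CHEBI:\d+$	Chemical Entities of Biological Interest
ncbigene	^\d+$	NCBI Gene
hgnc	^((HGNC|hgnc):)?\d{1,5}$	HUGO Gene Nomenclature Committee
go	^GO:\d{7}$	Gene Ontology
sbo	^SBO:\d{7}$	Systems Biology Ontology
pubmed	^\d+$	PubMed
doi	^10\.\d{4,9}/\S+$	Digital Object Identifier
pmc	^PMC\d+$	PubMed Central
reactome	^R-[A-Z]{3}-\d+(-\d+)?(\.\d+)?$	Reactome
ensembl	^ENS[A-Z]*[GTP]\d{11}(\.\d+)?$	Ensembl
interpro	^IPR\d{6}$	InterPro
pfam	^PF\d{5}$	Pfam
kegg.compound	^C\d+$	KEGG Compound
mesh	^[CD]\d{6,9}$	Medical Subject Headings
taxonomy	^\d+$	NCBI Taxonomy
ec-code	^\d+(\.(\d+|-)){3}$	Enzyme Nomenclature
pubchem.compound	^\d+$	PubChem Compound
hmdb	^HMDB\d+$	Human Metabolome Database
mirbase	^MI\d{7}$	miRBase
rhea	^\d{5}$	Rhea
cl	^CL:\d{7}$	Cell Ontology
uberon	^UBERON:\d+$	Uber Anatomy Ontology
mondo	^MONDO:\d{7}$	MONDO Disease Ontology
efo	^\d{7}$	Experimental Factor Ontology
wikipathways	^WP\d{1,5}(_r\d+)?$	WikiPathways
signor	^SIGNOR-[A-Z]+\d+$	SIGNOR
biogrid	^\d+$	BioGRID
mi	^MI:\d{4}$	Molecular Interactions Controlled Vocabulary
chembl.compound	^CHEMBL\d+$	ChEMBL Compound
drugbank	^DB\d{5}$	DrugBank
refseq	^[A-Z]{2}_\d+(\.\d+)?$	RefSeq
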