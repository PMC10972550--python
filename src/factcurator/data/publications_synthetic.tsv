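id_type	id_value	title	journal	year	authors
pmid	10000001	Ubiquitin-mediated turnover of a tumour suppressor in stressed cells	Synthetic Journal of Cell Regulation	2019	Adler K; Brandt L
pmid	10000002	Kinase-dependent phosphorylation controls transcription factor stability	Synthetic Molecular Biology Reports	2020	Cheng W; Dufort M; Eriksen P
pmid	10000003	A feedback loop between an E3 ligase and its substrate	Synthetic Signalling Letters	2018	Farkas A
pmid	12345	Binding of a RING-domain ligase to its target protein	Synthetic Biochemistry Notes	2004	Grigoras V; Hahn T
pmcid	PMC7000001	Compartmentalized degradation of nuclear proteins	Synthetic Open Cell Biology	2021	Ito R; Jensen O
doi	10.1000/synth.0001	Stoichiometry of modifier action in enzymatic ubiquitination	Synthetic Systems Biology	2022	Kovacs B; Lindgren S
doi	10.1000/synth.0002	Evidence aggregation for causal molecular statements	Synthetic Curation Methods	2023	Moreau C
pmid	10000004	Nuclear export of a ubiquitinated transcription factor	Synthetic Journal of Cell Regulation	2017	Novak D; Olsen E
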