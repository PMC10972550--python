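# BioModels qualifier vocabulary (closed list), one token per line.
bqbiol:encodes
bqbiol:hasPart
bqbiol:hasProperty
bqbiol:hasTaxon
bqbiol:hasVersion
bqbiol:is
bqbiol:isDescribedBy
bqbiol:isEncodedBy
bqbiol:isHomologTo
bqbiol:isPartOf
bqbiol:isPropertyOf
bqbiol:isVersionOf
bqbiol:occursIn
bqmodel:hasInstance
bqmodel:is
bqmodel:isDerivedFrom
bqmodel:isDescribedBy
bqmodel:isInstanceOf
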