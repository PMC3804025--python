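# Default vocabulary registry: 18 controlled vocabularies, routed to one of
# two annotator styles (13 ncbo_like, 5 whatizit_like); exactly 7 carry
# Bio2RDF/identifiers.org owl:sameAs link templates (ChEBI, GO, MeSH, NCIt,
# UniProt proteins, UniProt Taxonomy, NCBI Taxon).
# Reconciliation note: the source tooling names more NCBO ontologies than the
# published 13-count; this table keeps the 13/5 split, retaining the drug and
# disease terminologies (MDDB, NDFRT, SNOMED, SYMP, MedDRA, OMIM, FMA, ICD10,
# OBI) plus ChEBI, MeSH, NCIt and PO, and omitting Pathway, MGED, NDDF and
# MedlinePlus.  Columns are tab-separated; '-' means not applicable.
# key	display_name	route	bio2rdf_linked	entity_prefix	identifiersorg_template	bio2rdf_template	seealso_template
chebi	ChEBI	ncbo_like	true	http://purl.obolibrary.org/obo/CHEBI_	http://identifiers.org/chebi/CHEBI:{id}	http://bio2rdf.org/chebi:{id}	https://www.ebi.ac.uk/chebi/searchId.do?chebiId=CHEBI:{id}
mesh	MeSH	ncbo_like	true	http://purl.bioontology.org/ontology/MSH/	http://identifiers.org/mesh/{id}	http://bio2rdf.org/mesh:{id}	https://meshb.nlm.nih.gov/record/ui?ui={id}
ncit	NCIt	ncbo_like	true	http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl%23	http://identifiers.org/ncit/{id}	http://bio2rdf.org/ncit:{id}	https://ncit.nci.nih.gov/ncitbrowser/ConceptReport.jsp?code={id}
snomed	SNOMED CT	ncbo_like	false	http://purl.bioontology.org/ontology/SNOMEDCT/	-	-	https://bioportal.bioontology.org/ontologies/SNOMEDCT?p=classes&conceptid={id}
symp	Symptom Ontology	ncbo_like	false	http://purl.obolibrary.org/obo/SYMP_	-	-	https://bioportal.bioontology.org/ontologies/SYMP?p=classes&conceptid={id}
meddra	MedDRA	ncbo_like	false	http://purl.bioontology.org/ontology/MEDDRA/	-	-	https://bioportal.bioontology.org/ontologies/MEDDRA?p=classes&conceptid={id}
omim	OMIM	ncbo_like	false	http://purl.bioontology.org/ontology/OMIM/	-	-	https://omim.org/entry/{id}
fma	FMA	ncbo_like	false	http://purl.org/sig/ont/fma/fma	-	-	https://bioportal.bioontology.org/ontologies/FMA?p=classes&conceptid={id}
icd10	ICD-10	ncbo_like	false	http://purl.bioontology.org/ontology/ICD10/	-	-	https://bioportal.bioontology.org/ontologies/ICD10?p=classes&conceptid={id}
obi	OBI	ncbo_like	false	http://purl.obolibrary.org/obo/OBI_	-	-	https://bioportal.bioontology.org/ontologies/OBI?p=classes&conceptid={id}
po	Plant Ontology	ncbo_like	false	http://purl.obolibrary.org/obo/PO_	-	-	https://bioportal.bioontology.org/ontologies/PO?p=classes&conceptid={id}
mddb	MDDB	ncbo_like	false	http://purl.bioontology.org/ontology/MDDB/	-	-	https://bioportal.bioontology.org/ontologies/MDDB?p=classes&conceptid={id}
ndfrt	NDF-RT	ncbo_like	false	http://purl.bioontology.org/ontology/NDFRT/	-	-	https://bioportal.bioontology.org/ontologies/NDFRT?p=classes&conceptid={id}
go	Gene Ontology	whatizit_like	true	http://purl.obolibrary.org/obo/GO_	http://identifiers.org/go/GO:{id}	http://bio2rdf.org/go:{id}	https://amigo.geneontology.org/amigo/term/GO:{id}
uniprot	UniProt proteins	whatizit_like	true	http://purl.uniprot.org/uniprot/	http://identifiers.org/uniprot/{id}	http://bio2rdf.org/uniprot:{id}	https://www.uniprot.org/uniprotkb/{id}
uniprot_taxonomy	UniProt Taxonomy	whatizit_like	true	http://purl.uniprot.org/taxonomy/	http://identifiers.org/taxonomy/{id}	http://bio2rdf.org/taxonomy:{id}	https://www.uniprot.org/taxonomy/{id}
ncbi_taxon	NCBI Taxon	whatizit_like	true	http://purl.obolibrary.org/obo/NCBITaxon_	http://identifiers.org/taxonomy/{id}	http://bio2rdf.org/taxon:{id}	https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id={id}
umls_disease	UMLS diseases	whatizit_like	false	http://linkedlifedata.com/resource/umls/id/	-	-	https://uts.nlm.nih.gov/uts/umls/concept/{id}
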