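# Declarative rewrite table: bibliographic-graph vocabulary -> SIO, for
# Bio2RDF-compatible output.  Property lineage follows the SIO upper model:
# object properties map to sio:SIO_000008 "has attribute" except citing /
# referencing relations, which map to sio:SIO_000628 "refers to" and
# sio:SIO_000212 "is referenced by"; all data-type properties map to
# sio:SIO_000300 "has value".  Original domains and ranges are not enforced.
# The W3C PROV pair passes through unchanged: rewriting it onto the same SIO
# lineage as its DCMI twin would merge the dual provenance statements.
# NOTE: the class-target column is a RECONSTRUCTION — the published class
# correspondence is not available in machine-readable form, so the SIO class
# ids below are this package's own assignment and are editable here.
# Columns: source IRI <TAB> target IRI ('-' for passthrough) <TAB> kind
http://purl.org/ontology/bibo/Document	http://semanticscience.org/resource/SIO_000148	class
http://purl.org/ontology/bibo/AcademicArticle	http://semanticscience.org/resource/SIO_000154	class
http://purl.org/ontology/bibo/Journal	http://semanticscience.org/resource/SIO_000160	class
http://purl.org/spar/doco/Section	http://semanticscience.org/resource/SIO_000161	class
http://purl.org/spar/doco/Abstract	http://semanticscience.org/resource/SIO_000162	class
http://purl.org/spar/doco/Paragraph	http://semanticscience.org/resource/SIO_000163	class
http://www.w3.org/2011/content#ContentAsText	http://semanticscience.org/resource/SIO_000164	class
http://xmlns.com/foaf/0.1/Person	http://semanticscience.org/resource/SIO_000498	class
http://xmlns.com/foaf/0.1/Organization	http://semanticscience.org/resource/SIO_000012	class
http://www.w3.org/1999/02/22-rdf-syntax-ns#Seq	-	passthrough
http://purl.org/dc/terms/isPartOf	http://semanticscience.org/resource/SIO_000008	objprop
http://purl.org/dc/terms/hasPart	http://semanticscience.org/resource/SIO_000008	objprop
http://purl.org/dc/terms/creator	http://semanticscience.org/resource/SIO_000008	objprop
http://www.w3.org/ns/prov#wasAttributedTo	-	passthrough
http://purl.org/ontology/bibo/authorList	http://semanticscience.org/resource/SIO_000008	objprop
http://xmlns.com/foaf/0.1/member	http://semanticscience.org/resource/SIO_000008	objprop
http://xmlns.com/foaf/0.1/mbox	http://semanticscience.org/resource/SIO_000008	objprop
http://purl.org/ontology/bibo/cites	http://semanticscience.org/resource/SIO_000628	objprop
http://purl.org/ontology/bibo/citedBy	http://semanticscience.org/resource/SIO_000212	objprop
http://www.w3.org/2000/01/rdf-schema#seeAlso	http://semanticscience.org/resource/SIO_000628	objprop
http://purl.org/dc/terms/title	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/dc/terms/identifier	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/dc/terms/subject	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/dc/terms/publisher	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/dc/terms/created	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/dc/terms/source	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/dc/terms/date	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/dc/terms/bibliographicCitation	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/dc/terms/license	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/ontology/bibo/pmid	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/ontology/bibo/doi	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/ontology/bibo/issn	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/ontology/bibo/volume	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/ontology/bibo/issue	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/ontology/bibo/pageStart	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/ontology/bibo/pageEnd	http://semanticscience.org/resource/SIO_000300	dataprop
http://purl.org/ontology/bibo/pages	http://semanticscience.org/resource/SIO_000300	dataprop
http://xmlns.com/foaf/0.1/surname	http://semanticscience.org/resource/SIO_000300	dataprop
http://xmlns.com/foaf/0.1/givenName	http://semanticscience.org/resource/SIO_000300	dataprop
http://xmlns.com/foaf/0.1/name	http://semanticscience.org/resource/SIO_000300	dataprop
http://www.w3.org/2011/content#chars	http://semanticscience.org/resource/SIO_000300	dataprop
http://www.w3.org/ns/prov#generatedAtTime	-	passthrough
http://www.w3.org/2000/01/rdf-schema#comment	http://semanticscience.org/resource/SIO_000300	dataprop
http://www.w3.org/1999/02/22-rdf-syntax-ns#type	-	passthrough
http://www.w3.org/2002/07/owl#sameAs	-	passthrough
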