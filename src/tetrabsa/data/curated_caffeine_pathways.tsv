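substrate	pathway	ec_number	enzyme_label	metabolism_type	n_sequences	duplication_note
SAM	Cysteine and methionine metabolism	2.1.1.37	(cytosine-5-)-methyltransferase	A	1
XMP	Purine metabolism	6.3.5.2	synthase (glutamine-hydrolysing)	C	2
AMP	Purine metabolism	4.3.2.2	lyase	A	1
AICAR-SAICAR	Purine metabolism	4.3.2.2	lyase	A	1
FGAM	Purine metabolism	6.3.5.3	synthase	A	2
10-Formyl-THF	One carbon pool by folate	3.5.1.10	deformylase	A	1
Glutamate	Arginine biosynthesis	2.3.1.1	N-acetyltransferase	C	1	one sequence carries two SNPs
Glutamate	Arginine and proline metabolism	2.7.2.11	5-kinase	C	1
Glutamate	Carbapenem biosynthesis	2.7.2.11	5-kinase	C	1
Glutamate	Glutathione metabolism	2.5.1.18	transferase	A	1
ATP-ADP	Purine metabolism	3.6.1.15	phosphatase	A	29	the 24-sequence adenylpyrophosphatase row shares sequences with this row
ATP-ADP	Purine metabolism	3.6.1.3	adenylpyrophosphatase	A	24	shares sequences with the 29-sequence phosphatase row
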