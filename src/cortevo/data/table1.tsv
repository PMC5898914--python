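symbol	gene_id	occurrence	homo_sub	mechanism	datasets	is_znf
ANKRD20A2	ANKRD20A2	Homo	before_split	whole_duplication	Florio,Pollen,Miller	0
ANKRD20A4	ANKRD20A4	Homo	before_split	whole_duplication	Florio,Fietz,Pollen	0
ARHGAP11B	ARHGAP11B	Homo	before_split	partial_duplication	Florio,Fietz,Pollen	0
CBWD6	CBWD6	Homo	before_split	whole_duplication	Pollen,Miller	0
DHRS4L2	DHRS4L2	Homo	before_split	whole_duplication	Fietz,Pollen	0
FAM182B	FAM182B	Homo	before_split	stop_codon_loss	Fietz,Miller	0
FAM72B	FAM72B	Homo	before_split	whole_duplication	Florio,Fietz,Pollen	0
FAM72C	FAM72C	Homo	before_split	whole_duplication	Florio,Fietz,Pollen	0
FAM72D	FAM72D	Homo	before_split	whole_duplication	Florio,Fietz,Miller	0
GTF2H2C	GTF2H2C	Homo	before_split	whole_duplication	Pollen,Miller	1
NBPF10	NBPF10	Homo	before_split	whole_duplication	Fietz,Pollen	0
NBPF14	NBPF14	Homo	before_split	whole_duplication	Fietz,Pollen	0
NOTCH2NL	NOTCH2NL	Homo	before_split	whole_duplication	Florio,Fietz,Pollen	0
SMN2	SMN2	Homo	after_split	whole_duplication	Pollen,Miller	0
ZNF492	ZNF492	Homo	before_split	exon_replacement	Florio,Fietz,Pollen	1
ALG1L	ALG1L	Hominini		unknown	Pollen,Miller	0
CBWD2	CBWD2	Hominini		unknown	Pollen,Miller	0
TMEM133	TMEM133	Hominini		unknown	Fietz,Miller,Johnson	0
HHLA3	HHLA3	Homininae		unknown	Fietz,Pollen	0
TMEM99	TMEM99	Hominidae		unknown	Fietz,Miller	0
ZNF90	ZNF90	Hominidae		unknown	Florio,Pollen	1
CCDC74B	CCDC74B	Hominoidae		unknown	Fietz,Pollen,Miller,Johnson	0
C9orf47	C9orf47	Hominoidae		unknown	Fietz,Miller,Johnson	0
GLUD2	GLUD2	Hominoidae		retroposition	Miller,Johnson	0
PTTG2	PTTG2	Hominoidae		retroposition	Fietz,Miller	0
APOL2	APOL2	Catarrhini		unknown	Florio,Fietz,Pollen,Johnson	0
APOL4	APOL4	Catarrhini		unknown	Fietz,Miller	0
BTN3A2	BTN3A2	Catarrhini		unknown	Fietz,Pollen,Miller	0
BTN3A3	BTN3A3	Catarrhini		whole_duplication	Fietz,Miller	0
MICA	MICA	Catarrhini		whole_duplication	Florio,Fietz,Miller	0
MT1M	MT1M	Catarrhini		unknown	Miller,Johnson	0
SLFN13	SLFN13	Catarrhini		unknown	Florio,Johnson	0
ZNF100	ZNF100	Catarrhini		unknown	Fietz,Pollen	1
ZNF222	ZNF222	Catarrhini		unknown	Pollen,Miller	1
ZNF43	ZNF43	Catarrhini		unknown	Fietz,Pollen	1
ZNF695	ZNF695	Catarrhini		unknown	Florio,Fietz,Miller	1
ZNF724	ZNF724	Catarrhini		unknown	Florio,Fietz,Pollen	1
ZNF726	ZNF726	Catarrhini		unknown	Florio,Fietz	1
ZNF730	ZNF730	Catarrhini		unknown	Fietz,Johnson	1
ZNF732	ZNF732	Catarrhini		unknown	Florio,Pollen	1
ZNF816	ZNF816	Catarrhini		unknown	Florio,Fietz,Pollen,Miller	1
ZNF93	ZNF93	Catarrhini		unknown	Pollen,Miller	1
HEPN1	HEPN1	Simiiformes		unknown	Florio,Fietz,Miller	0
KIF4B	KIF4B	Simiiformes		retroposition	Fietz,Pollen	0
ZNF20	ZNF20	Simiiformes		unknown	Fietz,Miller	1
ZNF680	ZNF680	Simiiformes		unknown	Florio,Pollen	1
ZNF718	ZNF718	Simiiformes		unknown	Fietz,Pollen	1
ZNF788	ZNF788	Simiiformes		unknown	Fietz,Pollen	1
MT1E	MT1E	Haplorrhini		unknown	Pollen,Miller	0
TNFRSF10D	TNFRSF10D	Haplorrhini		unknown	Florio,Fietz	0
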