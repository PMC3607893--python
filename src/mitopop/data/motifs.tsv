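# mtDNA control-region haplogroup motif table (editable).
# Columns: clade, parent, motifs (semicolon-separated variant labels,
# empty for structural nodes), hvs_only (yes/no), source.
# source=printed: motif as printed in the revised L0d/L0k nomenclature this
#   package ships (new clades L0d2d, L0dx, L0d3a; 16300G, 523delCA removed
#   from L0d3; 16239T removed from L0d1b; 198T removed from L0d2a).
# source=curated: clade whose control-region motif is not printed in that
#   revision; shipped as an editable placeholder so the classifier stays
#   data-driven.  Edit this file (or pass your own) for production use.
clade	parent	motifs	hvs_only	source
L0	ROOT	16223T;16278T;16311C	yes	curated
L0a	L0	16148T;16172C;16320T	yes	curated
L0d	L0	16243C	yes	curated
L0k	L0	16214T	yes	curated
L0k1	L0k	16166C	yes	curated
L0d3	L0d	151T;16209C;16274A	yes	curated
L0d3a	L0d3	16129A;16274G!;16399G	yes	printed
L0d1'2	L0d	498delC;16278C!	yes	printed
L0d1	L0d1'2	523insCA	yes	printed
L0dx	L0d1'2	16179T;523insCA	yes	printed
L0d2	L0d1'2		no	printed
L0d1a	L0d1	16163G	yes	curated
L0d1b	L0d1	16294T	yes	printed
L0d1c	L0d1	16249C	yes	curated
L0d1c1	L0d1c	16234T	yes	curated
L0d2abd	L0d2	16212G	yes	printed
L0d2a	L0d2abd	597T;16390A	yes	printed
L0d2b	L0d2abd	16069T;16169T	yes	printed
L0d2d	L0d2abd	188G	yes	printed
L0d2c	L0d2	294A	yes	printed
L1	ROOT	16187T	no	curated
L2	ROOT	16192T	no	curated
L3	ROOT	16124C	no	curated
L4	ROOT	16362C	no	curated
L5	ROOT	16330C	no	curated
L6	ROOT	16048A	no	curated
M	ROOT	489C	no	curated
N	ROOT	150T	no	curated
R	ROOT	16519C	no	curated
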