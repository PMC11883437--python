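code	name	C	H	N	O	S
G	glycine	2	3	1	1	0
A	alanine	3	5	1	1	0
S	serine	3	5	1	2	0
P	proline	5	7	1	1	0
V	valine	5	9	1	1	0
T	threonine	4	7	1	2	0
C	cysteine	3	5	1	1	1
L	leucine	6	11	1	1	0
I	isoleucine	6	11	1	1	0
N	asparagine	4	6	2	2	0
D	aspartate	4	5	1	3	0
Q	glutamine	5	8	2	2	0
K	lysine	6	12	2	1	0
E	glutamate	5	7	1	3	0
M	methionine	5	9	1	1	1
H	histidine	6	7	3	1	0
F	phenylalanine	9	9	1	1	0
R	arginine	6	12	4	1	0
Y	tyrosine	9	9	1	2	0
W	tryptophan	11	10	2	1	0
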