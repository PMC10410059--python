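# PSEN1 (presenilin-1) membrane topology by protein codon, 9-transmembrane model.
# source: UniProt P49768 (PSEN1_HUMAN) topology annotation (TRANSMEM helices and
# TOPO_DOM cytoplasmic/lumenal segments). Labels: TM = transmembrane helix,
# CY = cytoplasmic topological domain, other = lumenal/extracellular segment.
# Columns: start_codon, end_codon (inclusive), label.
start	end	label
1	82	CY
83	103	TM
104	132	other
133	153	TM
154	169	CY
170	190	TM
191	194	other
195	215	TM
216	220	CY
221	241	TM
242	243	other
244	264	TM
265	380	CY
381	401	TM
402	407	other
408	428	TM
429	432	CY
433	453	TM
454	467	other
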