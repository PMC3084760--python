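anchor_id	feature	role	position
HCO_anchor	d_channel	Tyr35	35
HCO_anchor	d_channel	Asn113	113
HCO_anchor	d_channel	Asp124	124
HCO_anchor	d_channel	Asn131	131
HCO_anchor	d_channel	Ser134	134
HCO_anchor	d_channel	Ser193	193
HCO_anchor	d_channel	Asn199	199
HCO_anchor	d_channel	Glu278	278
HCO_anchor	k_channel	Tyr280	280
HCO_anchor	k_channel	Ser291	291
HCO_anchor	k_channel	Thr351	351
HCO_anchor	k_channel	Lys354	354
HCO_anchor	his_ligand	His94	94
HCO_anchor	his_ligand	His276	276
HCO_anchor	his_ligand	His325	325
HCO_anchor	his_ligand	His326	326
HCO_anchor	his_ligand	His411	411
HCO_anchor	his_ligand	His413	413
HCO_anchor	tyrII_region	-	430-460
NOR_anchor	his_ligand	His94	94
NOR_anchor	his_ligand	His276	276
NOR_anchor	his_ligand	His325	325
NOR_anchor	his_ligand	His326	326
NOR_anchor	his_ligand	His411	411
NOR_anchor	his_ligand	His413	413
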