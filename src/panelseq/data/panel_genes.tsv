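gene	transcript_id
APC	NM_000038.5
ATM	NM_000051.3
BARD1	NM_000465.3
BMPR1A	NM_004329.2
BRCA1	NM_007294.3
BRCA2	NM_000059.3
BRIP1	NM_032043.2
CDH1	NM_004360.3
CDK4	NM_000075.3
CHEK2	NM_007194.3
EPCAM	NM_002354.2
MLH1	NM_000249.3
MSH2	NM_000251.2
MSH6	NM_000179.2
MUTYH_alpha5	NM_001128425.1
MUTYH_alpha3	NM_001048171.1
NBN	NM_002485.4
P14ARF	NM_058195.3
P16	NM_000077.4
PALB2	NM_024675.3
PMS2	NM_000535.5
PTEN	NM_000314.4
RAD51C	NM_058216.2
RAD51D	NM_002878.3
SMAD4	NM_005359.5
STK11	NM_000455.4
TP53	NM_000546.5
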