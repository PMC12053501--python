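# Gene-name synonym table: alias <TAB> canonical name.
# Aliases are matched case-insensitively with whitespace collapsed.
# Canonical names also match themselves case-insensitively.
ndh1	ndhA
ndh2	ndhB
ndh3	ndhC
ndh4	ndhD
ndh4l	ndhE
ndh5	ndhF
ndh6	ndhG
ndh7	ndhH
nad1	ndhA
nadh dehydrogenase subunit 1	ndhA
nadh dehydrogenase subunit 2	ndhB
nadh dehydrogenase subunit 3	ndhC
nadh dehydrogenase subunit 4	ndhD
nadh dehydrogenase subunit 4l	ndhE
nadh dehydrogenase subunit 5	ndhF
nadh dehydrogenase subunit 6	ndhG
nadh dehydrogenase subunit 7	ndhH
nadh dehydrogenase subunit i	ndhI
nadh dehydrogenase subunit j	ndhJ
nadh dehydrogenase subunit k	ndhK
nadh-plastoquinone oxidoreductase subunit 1	ndhA
nadh-plastoquinone oxidoreductase subunit 2	ndhB
nadh-plastoquinone oxidoreductase subunit 3	ndhC
nadh-plastoquinone oxidoreductase subunit 4	ndhD
nadh-plastoquinone oxidoreductase subunit 4l	ndhE
nadh-plastoquinone oxidoreductase subunit 5	ndhF
nadh-plastoquinone oxidoreductase subunit 6	ndhG
nadh-plastoquinone oxidoreductase subunit 7	ndhH
nadh-plastoquinone oxidoreductase subunit i	ndhI
nadh-plastoquinone oxidoreductase subunit j	ndhJ
nadh-plastoquinone oxidoreductase subunit k	ndhK
ndha	ndhA
ndhb	ndhB
ndhc	ndhC
ndhd	ndhD
ndhe	ndhE
ndhf	ndhF
ndhg	ndhG
ndhh	ndhH
ndhi	ndhI
ndhj	ndhJ
ndhk	ndhK
# A few common plastid genes so canonical capitalization survives round-trips.
rbcl	rbcL
matk	matK
psba	psbA
atpb	atpB
rpob	rpoB
rpoc1	rpoC1
rpoc2	rpoC2
accd	accD
ycf1	ycf1
ycf2	ycf2
clpp	clpP
ribulose-1,5-bisphosphate carboxylase/oxygenase large subunit	rbcL
maturase k	matK
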