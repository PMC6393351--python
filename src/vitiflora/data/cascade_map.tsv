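# Sesquiterpene -> carbocation cascade class.
# Classes: farnesyl (direct deprotonation of the farnesyl cation, linear
# farnesenes), humulyl (1,11-ring closure: humulenes, caryophyllenes),
# germacradienyl ((E,E)-germacradienyl cation via 1,10-closure: selinenes,
# valencene, germacrenes, elemenes), nerolidyl_bisabolyl (FPP->NPP
# isomerisation, nerolidyl/bisabolyl cations).
# PROVISIONAL assignments (mechanism not settled in the terpene literature
# consulted; edit freely): gamma-cadinene, alpha-amorphene -> germacradienyl;
# camphene -> nerolidyl_bisabolyl.
compound	cation_class
(E)-beta-farnesene	farnesyl
(E,E)-alpha-farnesene	farnesyl
beta-caryophyllene	humulyl
(E)-beta-caryophyllene	humulyl
alpha-humulene	humulyl
(+)-valencene	germacradienyl
alpha-selinene	germacradienyl
beta-selinene	germacradienyl
gamma-selinene	germacradienyl
7-epi-alpha-selinene	germacradienyl
germacrene A	germacradienyl
germacrene D	germacradienyl
beta-elemene	germacradienyl
gamma-cadinene	germacradienyl
alpha-amorphene	germacradienyl
(+)-aromadendrene	germacradienyl
(Z,E)-alpha-farnesene	nerolidyl_bisabolyl
alpha-bergamotene	nerolidyl_bisabolyl
camphene	nerolidyl_bisabolyl
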