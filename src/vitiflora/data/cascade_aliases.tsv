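# Naming variants -> canonical compound names (case-insensitive on lookup).
# Greek letters are accepted alongside their spelled-out forms; the two
# distinct beta-selinene rows of the packaged product-profile table are kept
# apart in that table but share one cascade class here.
alias	compound
(E)-β-farnesene	(E)-beta-farnesene
(E,E)-α-farnesene	(E,E)-alpha-farnesene
(Z,E)-α-farnesene	(Z,E)-alpha-farnesene
β-caryophyllene	beta-caryophyllene
(E)-β-caryophyllene	(E)-beta-caryophyllene
α-humulene	alpha-humulene
valencene	(+)-valencene
α-selinene	alpha-selinene
β-selinene	beta-selinene
γ-selinene	gamma-selinene
beta-selinene (a)	beta-selinene
beta-selinene (b)	beta-selinene
β-selinene (a)	beta-selinene
β-selinene (b)	beta-selinene
7-epi-α-selinene	7-epi-alpha-selinene
β-elemene	beta-elemene
γ-cadinene	gamma-cadinene
α-amorphene	alpha-amorphene
aromadendrene	(+)-aromadendrene
α-bergamotene	alpha-bergamotene
bergamotene	alpha-bergamotene
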