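# Percentage contribution of volatiles produced by heterologous (in vivo
# yeast) expression of VvivTPS cultivar variants, as printed in the source
# study's product table.  The table prints two distinct beta-Selinene rows;
# both are preserved here as "beta-Selinene (a)" / "beta-Selinene (b)"
# (suspected typo in the original, documented rather than corrected).
# Empty cells mean the enzyme did not produce that volatile.
compound,VvivSBTPS01,VvivMATPS01,VvivSBTPS02,VvivMATPS10,VvivSHTPS27,VvivMATPS27,VvivMATPS28
beta-Elemene,6.2,5.5,,,,,
(E)-beta-Caryophyllene,,,100.0,,69.1,63.7,
(E)-beta-Farnesene,,,,100.0,,,
alpha-Humulene,5.3,7.4,,,,,
beta-Selinene (a),,,,,22.9,24.2,
gamma-Selinene,6.3,,,,,,
Germacrene D,,,,,2.7,3.7,56.4
beta-Selinene (b),16.4,15.1,,,,,
alpha-Selinene,38.1,49.1,,,,,
Camphene,,,,,,,12.1
gamma-Cadinene,,,,,1.1,1.6,17.6
alpha-Amorphene,,,,,,,13.9
Germacrene A,23.6,20.0,,,0.9,1.4,
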