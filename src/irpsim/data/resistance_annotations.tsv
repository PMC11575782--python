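# Clinical resistance association per variant x drug. "resistant": the
# mutation alone is associated with resistance to the drug; "compound_only":
# the mutation raises IC50 but confers resistance only within a compound
# (double) mutation — applies to ponatinib; "sensitive": no resistance
# association. Compound variants inherit "resistant" when they contain a
# component that is resistance-associated (alone or as compound_only).
variant	imatinib	ponatinib	dasatinib
Wild-type	sensitive	sensitive	sensitive
G250E	resistant	sensitive	sensitive
Y253H	resistant	sensitive	sensitive
E255K	resistant	compound_only	sensitive
E255V	resistant	compound_only	sensitive
T315I	resistant	compound_only	resistant
T315M	resistant	resistant	resistant
G250E-T315I	resistant	resistant	resistant
Y253H-E255V	resistant	resistant	sensitive
Y253H-T315I	resistant	resistant	resistant
E255V-T315I	resistant	resistant	resistant
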