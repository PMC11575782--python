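# Measured catalytic parameters and IC50 values for wild-type Abl1 and ten
# kinase-domain mutants, compiled from published enzymology and inhibition
# assays. kcat and KM characterise substrate turnover; IC50 columns give the
# half-inhibition concentration per drug. atp_site_mutant marks variants with
# a substitution at or bordering the ATP-binding pocket (position 315), which
# changes how ATP-competitive active-state binders associate.
variant	kcat_per_min	KM_uM	ic50_imatinib_nM	ic50_ponatinib_nM	ic50_dasatinib_nM	atp_site_mutant
Wild-type	66	17	527.0	2.1	1.8	false
G250E	175.2	14.3	3613.0	12.5	8.1	false
Y253H	26.9	4.6	4589	29.8	5.9	false
E255K	63.6	15.6	3174	17.6	10.3	false
E255V	6.8	22.1	8953	27.2	6.3	false
T315I	12.2	7.2	9221	6.3	137.3	true
T315M	8.1	1.9	10240	577.5	768	true
G250E-T315I	30.0	1.0	10240	152.4	768	true
Y253H-E255V	13.2	0.7	10240	203.5	18.1	false
Y253H-T315I	3.8	0.5	10240	357.9	768	true
E255V-T315I	4.1	0.6	10240	659.5	768	true
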