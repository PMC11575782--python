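# One-compartment oral pharmacokinetic inputs per drug: absorption rate
# constant ka, elimination half-life and rate constant ke = ln2/t_half,
# daily dose (mass and moles via molar mass M), volume of distribution Vd,
# dosing interval tau, and bioavailability F (assumed 1 for all drugs).
# gamma_nM, alpha and epsilon are the derived dosing constants
# (Gamma = F*D*ka/(Vd*(ka-ke)); alpha = exp(ka*tau); epsilon = exp(ke*tau))
# as printed in the source data; "printed" PK mode uses them verbatim.
drug	ka_per_h	t_half_e_h	ke_per_h	D_mg	M_g_mol	D_umol	Vd_L	tau_h	F	gamma_nM	alpha	epsilon
imatinib	0.94	18	0.0385	400	493.603	810.4	435	24	1	2112.46	6.28e9	2.52
ponatinib	1.302	24	0.0289	45	532.6	84.49	1223	24	1	70.65	3.72e13	2
dasatinib	1.74	4	0.173	180	488.01	368.8	2502	24	1	163.73	1.37e18	64
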