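# Free-energy-perturbation estimates of the alchemical WT->mutant free
# energies in the active and inactive conformations, and the resulting shift
# ddG of the inactive->active conformational free-energy difference upon
# mutation (kcal/mol). Consumed as constants; the wild-type shift is 0 by
# definition. Variants listed here are the ones simulated dynamically.
variant	dG_wt_to_mut_active_kcal_mol	dG_wt_to_mut_inactive_kcal_mol	ddG_kcal_mol
Wild-type			0.0
G250E	-60.45	-62.66	-2.2
E255K	65.60	65.11	-0.5
E255V	57.12	56.77	-0.4
T315I	29.72	29.82	0.1
T315M	28.40	28.50	0.1
Y253H-E255V	56.66	57.06	0.4
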