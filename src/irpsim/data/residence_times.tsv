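# Inhibitor residence times on wild-type Abl1 and the unbinding rate
# constants used by the model, with each drug's conformational binding mode
# (imatinib and ponatinib bind only the inactive kinase conformation,
# dasatinib only the active one). NOTE: the printed dasatinib pair is
# internally inconsistent (1/249 min = 0.00402 min^-1, not 0.00233); all
# downstream derived binding constants are consistent only with the printed
# koffR column, so the pipeline uses koffR_per_min as shipped.
drug	binding_mode	tR_min	koffR_per_min
imatinib	inactive_binder	17	0.059
ponatinib	inactive_binder	205	0.00488
dasatinib	active_binder	249	0.00233
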