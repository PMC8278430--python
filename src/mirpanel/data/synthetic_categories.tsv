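pathway_id	category
SYN_CHOLINERGIC	synaptic
SYN_DOPAMINERGIC	synaptic
SYN_GABAERGIC	synaptic
SYN_GLUTAMATERGIC	synaptic
NEUROACTIVE_LR	synaptic
AXON_GUIDANCE	neurodevelopment
LTP	neurodevelopment
MAPK_SIGNALING	signal_transduction
CALCIUM_SIGNALING	signal_transduction
WNT_SIGNALING	signal_transduction
INSULIN_SIGNALING	signal_transduction
GAP_JUNCTION	signal_transduction
ALZHEIMERS	disease
CANCER_PATHWAYS	disease
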