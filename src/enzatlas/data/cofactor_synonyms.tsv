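canonical_id	class
nad	NAD_linked
nadh	NAD_linked
nad+	NAD_linked
nadp	NADP_linked
nadph	NADP_linked
nadp+	NADP_linked
akg	aminotransferase
2-oxoglutarate	aminotransferase
2oxoglutarate	aminotransferase
alpha-ketoglutarate	aminotransferase
oxoglutarate	aminotransferase
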