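# Example drug -> indication-category map for confounding annotation.
# SYNTHETIC illustrative mapping compiled from general clinical knowledge;
# user-editable and meant to be replaced by an institution's own mapping.
# Categories: autoimmune, reproductive_tract_infection, metabolic,
# thyroid, progestogen_use.
ADALIMUMAB: [autoimmune]
INFLIXIMAB: [autoimmune]
CERTOLIZUMAB PEGOL: [autoimmune]
ETANERCEPT: [autoimmune]
NATALIZUMAB: [autoimmune]
VEDOLIZUMAB: [autoimmune]
FINGOLIMOD: [autoimmune]
INTERFERON BETA-1A: [autoimmune]
RISANKIZUMAB: [autoimmune]
METFORMIN: [metabolic]
INSULIN: [metabolic]
LEVOTHYROXINE: [thyroid]
METRONIDAZOLE: [reproductive_tract_infection]
AZITHROMYCIN: [reproductive_tract_infection]
LEVONORGESTREL: [progestogen_use]
ETONOGESTREL: [progestogen_use]
MEDROXYPROGESTERONE: [progestogen_use]
PROGESTERONE: [progestogen_use]
ULIPRISTAL: [progestogen_use]
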