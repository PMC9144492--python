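name,cas,tm_K,hfus,hfus_unit
benzamide,55-21-0,401.0,20.9,kJ/mol
salicylamide,65-45-2,412.3,28.4,kJ/mol
ethenzamide,938-73-8,405.0,20.4,kJ/mol
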