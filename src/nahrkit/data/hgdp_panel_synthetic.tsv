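population	individual	allele1	allele2
Biaka	Biaka_01	A	B
Biaka	Biaka_02	A	B
Biaka	Biaka_03	A	B
Biaka	Biaka_04	B	B
Biaka	Biaka_05	B	B
Biaka	Biaka_06	B	B
Biaka	Biaka_07	B	B
Mbuti	Mbuti_01	A	B
Mbuti	Mbuti_02	A	B
Mbuti	Mbuti_03	A	B
Mbuti	Mbuti_04	B	B
Mbuti	Mbuti_05	B	B
Mbuti	Mbuti_06	B	B
Druze	Druze_01	A	B
Druze	Druze_02	A	B
Druze	Druze_03	A	B
Druze	Druze_04	B	B
Druze	Druze_05	B	B
Druze	Druze_06	B	B
Bedouin	Bedouin_01	A	B
Bedouin	Bedouin_02	A	B
Bedouin	Bedouin_03	B	B
Bedouin	Bedouin_04	B	B
Bedouin	Bedouin_05	B	B
Bedouin	Bedouin_06	B	B
Basque	Basque_01	A	B
Basque	Basque_02	A	B
Basque	Basque_03	A	B
Basque	Basque_04	B	B
Basque	Basque_05	B	B
Basque	Basque_06	B	B
Han	Han_01	A	B
Han	Han_02	A	B
Han	Han_03	B	B
Han	Han_04	B	B
Han	Han_05	B	B
Han	Han_06	B	B
Yakut	Yakut_01	A	B
Yakut	Yakut_02	A	B
Yakut	Yakut_03	A	B
Yakut	Yakut_04	B	B
Yakut	Yakut_05	B	B
Yakut	Yakut_06	B	B
Karitiana	Karitiana_01	A	B
Karitiana	Karitiana_02	A	B
Karitiana	Karitiana_03	B	B
Karitiana	Karitiana_04	B	B
Karitiana	Karitiana_05	B	B
Karitiana	Karitiana_06	B	B
Maya	Maya_01	A	B
Maya	Maya_02	A	B
Maya	Maya_03	A	B
Maya	Maya_04	B	B
Maya	Maya_05	B	B
Maya	Maya_06	B	B
Melanesian	Melanesian_01	A	B
Melanesian	Melanesian_02	A	B
Melanesian	Melanesian_03	B	B
Melanesian	Melanesian_04	B	B
Melanesian	Melanesian_05	B	B
Melanesian	Melanesian_06	B	B
Melanesian	Melanesian_07	B	B
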