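# Lung-cancer-related GWAS Catalog trait strings (narrow vocabulary).
# One exact trait per line; matching is case-sensitive after whitespace
# normalization. Edit freely to adapt to other catalog releases.
Pulmonary function
Lung adenocarcinoma
Lung cancer
Lung cancer (DNA repair capacity)
Lung cancer (smoking interaction)
Non-small cell lung cancer
Non-small cell lung cancer (recurrence rate)
Non-small cell lung cancer (survival)
Response to platinum-based agents
Response to platinum-based chemotherapy (carboplatin)
Response to platinum-based chemotherapy (cisplatin)
Response to platinum-based chemotherapy in non-small-cell lung cancer
Adverse response to chemotherapy (neutropenia/leucopenia) (cisplatin)
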