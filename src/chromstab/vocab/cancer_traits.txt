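# Cancer-related GWAS Catalog trait strings (broad vocabulary); a
# superset of the lung vocabulary. One exact trait per line; matching is
# case-sensitive after whitespace normalization. A few entries with an
# unbalanced parenthesis reproduce truncations in the source list.
Adverse response to chemotherapy (neutropenia/leucopenia) (cisplatin)
Adverse response to chemotherapy in breast cancer (alopecia)
Adverse response to chemotherapy in breast cancer (alopecia) (anti-microtubule)
Adverse response to chemotherapy in breast cancer (alopecia) (cyclophosphamide+doxorubicin+/-5FU)
Adverse response to chemotherapy in breast cancer (alopecia) (cyclophosphamide+epirubicin+/-5FU)
Adverse response to chemotherapy in breast cancer (alopecia) (docetaxel)
Adverse response to chemotherapy in breast cancer (alopecia) (paclitaxel)
Anthracycline-induced cardiotoxicity in childhood cancer
Bladder cancer
Bladder cancer (smoking interaction)
Body mass index (change over time) in cancer
Body mass index (change over time) in cancer or chronic obstructive pulmonary disease
Body mass index (change over time) in gastrointestinal cancer
Body mass index (change over time) in gastrointestinal cancer or chronic obstructive pulmonary disease
Body mass index (change over time) in lung cancer
Body mass index (change over time) in lung cancer or chronic obstructive pulmonary disease
Breast cancer
Breast cancer (early onset)
Breast cancer (estrogen-receptor negative
Breast cancer (estrogen-receptor negative)
Breast cancer (estrogen-receptor positive)
Breast cancer (male)
Breast cancer (menopausal hormone therapy interaction)
Breast cancer (prognosis)
Breast cancer (survival)
Breast Cancer in BRCA1 mutation carriers
Breast cancer in BRCA2 mutation carriers
Breast cancer-free interval (treatment with aromatase inhibitor)
Cancer
Cancer (pleiotropy)
Cardia gastric cancer
Cervical cancer
Colon cancer
Colorectal cancer
Colorectal cancer (alcohol consumption interaction)
Colorectal cancer (aspirin and/or NSAID use interaction)
Colorectal cancer (calcium intake interaction)
Colorectal cancer (diet interaction)
Colorectal cancer (interaction)
Colorectal cancer (oestrogen-progestogen hormone therapy interaction)
Colorectal or endometrial cancer
Disease-free survival in breast cancer
Docetaxel-induced peripheral neuropathy in metastatic castrate-resistant prostate cancer
Endometrial cancer
Epithelial ovarian cancer
Erectile dysfunction and prostate cancer treatment
Esophageal cancer
Esophageal cancer (alcohol interaction)
Esophageal cancer (squamous cell)
Esophageal cancer and gastric cancer
Esophageal squamous cell cancer (length of survival)
Estradiol plasma levels (breast cancer)
Estrogen receptor status in breast cancer
Estrogen receptor status in HER2 negative breast cancer
Estrone conjugates/estrone ratio in resected early stage estrogen-receptor positive breast cancer
Estrone/androstenedione ratio in resected early stage-receptor positive breast cancer
Gallbladder cancer
Gastric cancer
Lobular breast cancer (menopausal hormone therapy interaction)
Lung adenocarcinoma
Lung cancer
Lung cancer (asbestos exposure interaction)
Lung cancer (DNA repair capacity)
Lung cancer (smoking interaction)
Multiple cancers (lung cancer
Multiple keratinocyte cancers
Non-cardia gastric cancer
Non-melanoma skin cancer
Non-small cell lung cancer
Non-small cell lung cancer (recurrence rate)
Non-small cell lung cancer (survival)
Obesity in adult survivors of childhood cancer exposed to cranial radiation
Obesity in adult survivors of childhood cancer not exposed to cranial radiation
Oral cavity and pharyngeal cancer
Oral cavity cancer
Oropharynx cancer
Ovarian cancer
Ovarian cancer in BRCA1 mutation carriers
Pancreatic cancer
Plasma androstenedione levels in resected early stage-receptor positive breast cancer
Plasma estrone conjugates levels in resected early stage estrogen-receptor positive breast cancer
Plasma estrone levels in resected estrogen-receptor positive breast cancer
Platinum-induced myelosuppression in non-small cell lung cancer
Progression free survival in metastatic colorectal cancer (CAPOX-B vs CAPOX-B plus cetuximab)
Progression free survival in metastatic colorectal cancer (treatment interaction)
Prostate cancer
Prostate cancer (early onset)
Prostate cancer (interaction)
Prostate cancer (survival)
Prostate cancer aggressiveness
Pulmonary function
Response to carboplatin and paclitaxel in ovarian cancer (Caspase 3/7 EC50)
Response to carboplatin and paclitaxel in ovarian cancer (MTT IC50)
Response to carboplatin in ovarian cancer (MTT IC50)
Response to chemotherapy in breast cancer (hypertension) (bevacizumab)
Response to chemotherapy in breast cancer hypertensive cases (cumulative dose) (bevacizumab)
Response to gemcitabine in pancreatic cancer
Response to irinotecan and platinum-based chemotherapy in non-small-cell lung cancer
Response to irinotecan in non-small-cell lung cancer
Response to paclitaxel in ovarian cancer (Caspase 3/7 EC50)
Response to paclitaxel in ovarian cancer (MTT IC50)
Response to Pazopanib in cancer (hepatotoxicity)
Response to platinum-based agents
Response to platinum-based chemotherapy (carboplatin)
Response to platinum-based chemotherapy (cisplatin)
Response to platinum-based chemotherapy in non-small-cell lung cancer
Response to platinum-based neoadjuvant chemotherapy in cervical cancer
Response to radiotherapy in cancer (late toxicity)
Response to radiotherapy in prostate cancer (overall toxicity)
Response to radiotherapy in prostate cancer (toxicity
Response to radiotherapy in prostate cancer (toxicity)
Response to tamoxifen in breast cancer
Small-cell lung cancer (survival)
Survival in colon cancer
Survival in colorectal cancer
Survival in colorectal cancer (distant metastatic)
Survival in colorectal cancer (non-distant metastatic)
Survival in endocrine treated breast cancer (estrogen-receptor positive)
Survival in head and neck cancer
Survival in microsatellite instability low/stable colorectal cancer
Survival in rectal cancer
Testicular cancer
Testicular germ cell cancer
Thyroid cancer
Thyroid cancer (Papillary
Urinary bladder cancer
Urinary symptoms in response to radiotherapy in prostate cancer
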