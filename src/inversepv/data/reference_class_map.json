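{
  "classes": {
    "Lenalidomide": "immunomodulatory agent",
    "Risperidone": "antipsychotic",
    "Levetiracetam": "antiepileptic",
    "Dulaglutide": "GLP-1 receptor agonist",
    "Insulin lispro": "insulin",
    "Varenicline": "smoking-cessation agent",
    "Dupilumab": "immunomodulatory monoclonal antibody",
    "Cyclophosphamide": "cytotoxic immunosuppressant",
    "Clozapine": "antipsychotic",
    "Valsartan": "angiotensin receptor blocker",
    "Insulin glargine": "insulin",
    "Fingolimod": "S1P receptor modulator",
    "Lamotrigine": "antiepileptic",
    "Rivaroxaban": "anticoagulant",
    "Carvedilol": "beta-blocker",
    "Carbamazepine": "antiepileptic",
    "Aripiprazole": "antipsychotic",
    "Enoxaparin": "anticoagulant",
    "Dimethyl fumarate": "immunomodulatory agent",
    "Atorvastatin calcium": "statin",
    "Insulin": "insulin",
    "Apixaban": "anticoagulant",
    "Insulin aspart": "insulin",
    "Apremilast": "PDE4 inhibitor",
    "Lisinopril": "ACE inhibitor",
    "Somatotropin": "growth hormone",
    "Clopidogrel": "antiplatelet",
    "Simvastatin": "statin",
    "Empagliflozin": "SGLT2 inhibitor",
    "Warfarin": "anticoagulant",
    "Diazepam": "benzodiazepine",
    "Fenofibrate": "fibrate",
    "Liraglutide": "GLP-1 receptor agonist",
    "Nifedipine": "calcium channel blocker",
    "Imatinib": "tyrosine kinase inhibitor",
    "Enalapril": "ACE inhibitor",
    "Fexofenadine": "antihistamine",
    "Spironolactone": "diuretic",
    "Metformin": "biguanide antidiabetic",
    "Glatiramer acetate": "immunomodulatory agent",
    "Hydroxyzine": "antihistamine",
    "Sitagliptin": "DPP-4 inhibitor",
    "Clonidine": "alpha-2 agonist",
    "Metoclopramide": "prokinetic antiemetic",
    "Pravastatin": "statin",
    "Losartan": "angiotensin receptor blocker",
    "Pregabalin": "antiepileptic",
    "Naltrexone": "opioid antagonist",
    "Verapamil": "calcium channel blocker",
    "Alprazolam": "benzodiazepine",
    "Metoprolol": "beta-blocker",
    "Topiramate": "antiepileptic",
    "Rosuvastatin calcium": "statin",
    "Fluconazole": "antifungal",
    "Gabapentin": "antiepileptic",
    "Interferon beta-1a": "interferon immunomodulator",
    "Nitroglycerin": "nitrate vasodilator",
    "Octreotide": "somatostatin analogue",
    "Atorvastatin": "statin",
    "Quetiapine": "antipsychotic",
    "Irbesartan": "angiotensin receptor blocker",
    "Atenolol": "beta-blocker",
    "Semaglutide": "GLP-1 receptor agonist",
    "Diltiazem": "calcium channel blocker",
    "Propranolol": "beta-blocker",
    "Allopurinol": "xanthine oxidase inhibitor",
    "Amlodipine": "calcium channel blocker",
    "Melatonin": "hormone supplement",
    "Temazepam": "benzodiazepine",
    "Clonazepam": "benzodiazepine",
    "Famotidine": "H2 antagonist",
    "Venlafaxine": "antidepressant",
    "Bisoprolol": "beta-blocker"
  },
  "designated": [
    "PDE4 inhibitor",
    "S1P receptor modulator",
    "cytotoxic immunosuppressant",
    "immunomodulatory agent",
    "immunomodulatory monoclonal antibody",
    "interferon immunomodulator",
    "tyrosine kinase inhibitor"
  ]
}
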