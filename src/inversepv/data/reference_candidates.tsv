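drug	ror	ci_low	ci_high
Lenalidomide	0.056	0.043	0.073
Risperidone	0.129	0.096	0.173
Levetiracetam	0.170	0.129	0.225
Dulaglutide	0.181	0.136	0.242
Insulin lispro	0.206	0.161	0.263
Varenicline	0.207	0.16	0.268
Dupilumab	0.213	0.185	0.245
Cyclophosphamide	0.215	0.175	0.265
Clozapine	0.225	0.182	0.280
Valsartan	0.240	0.206	0.280
Insulin glargine	0.246	0.205	0.295
Fingolimod	0.261	0.205	0.334
Lamotrigine	0.262	0.211	0.326
Rivaroxaban	0.287	0.242	0.341
Carvedilol	0.297	0.235	0.375
Carbamazepine	0.313	0.236	0.414
Aripiprazole	0.318	0.263	0.386
Enoxaparin	0.319	0.239	0.424
Dimethyl fumarate	0.332	0.275	0.400
Atorvastatin calcium	0.334	0.262	0.425
Insulin	0.340	0.295	0.390
Apixaban	0.348	0.305	0.396
Insulin aspart	0.349	0.267	0.455
Apremilast	0.357	0.296	0.431
Lisinopril	0.364	0.318	0.416
Somatotropin	0.373	0.279	0.498
Clopidogrel	0.385	0.329	0.452
Simvastatin	0.394	0.343	0.452
Empagliflozin	0.400	0.311	0.514
Warfarin	0.415	0.359	0.479
Diazepam	0.418	0.343	0.510
Fenofibrate	0.418	0.307	0.567
Liraglutide	0.419	0.319	0.552
Nifedipine	0.419	0.311	0.566
Imatinib	0.423	0.339	0.527
Enalapril	0.430	0.325	0.567
Fexofenadine	0.435	0.346	0.545
Spironolactone	0.442	0.364	0.537
Metformin	0.446	0.407	0.489
Glatiramer acetate	0.446	0.352	0.565
Hydroxyzine	0.454	0.346	0.594
Sitagliptin	0.460	0.376	0.563
Clonidine	0.465	0.355	0.609
Metoclopramide	0.472	0.377	0.592
Pravastatin	0.478	0.381	0.600
Losartan	0.488	0.422	0.565
Pregabalin	0.496	0.442	0.557
Naltrexone	0.499	0.370	0.673
Verapamil	0.501	0.372	0.673
Alprazolam	0.532	0.463	0.610
Metoprolol	0.552	0.497	0.612
Topiramate	0.566	0.472	0.680
Rosuvastatin calcium	0.570	0.427	0.761
Fluconazole	0.586	0.457	0.753
Gabapentin	0.591	0.535	0.654
Interferon beta-1a	0.594	0.533	0.662
Nitroglycerin	0.597	0.459	0.776
Octreotide	0.599	0.458	0.782
Atorvastatin	0.603	0.551	0.661
Quetiapine	0.606	0.539	0.681
Irbesartan	0.613	0.482	0.779
Atenolol	0.618	0.526	0.726
Semaglutide	0.622	0.507	0.764
Diltiazem	0.624	0.514	0.758
Propranolol	0.624	0.509	0.764
Allopurinol	0.638	0.546	0.745
Amlodipine	0.641	0.589	0.698
Melatonin	0.648	0.480	0.874
Temazepam	0.694	0.512	0.939
Clonazepam	0.745	0.658	0.844
Famotidine	0.780	0.655	0.930
Venlafaxine	0.852	0.757	0.960
Bisoprolol	0.856	0.754	0.972
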