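concept_id	preferred_term	synonyms	housing_related
HL0001	Homelessness	homeless	1
HL0002	Unstable housing	unstable housing situation	1
HL0003	Housing instability	housing insecurity|housing insecure	1
HL0004	Emergency shelter	homeless shelter	1
HL0005	Transitional housing		1
HL0006	Inadequate housing	substandard housing	1
HL0007	Living on the streets	street dwelling	1
HL0008	Unhoused		1
HL0009	Housing problem	housing problems	1
HL0010	Lack of housing		1
HL0011	Eviction	evicted	1
HL0012	Supportive housing		1
MD0001	Diabetes mellitus	DM|diabetes	0
MD0002	Hypertension	HTN|high blood pressure	0
MD0003	Asthma		0
MD0004	Chronic obstructive pulmonary disease	COPD	0
MD0005	Pneumonia		0
MD0006	Congestive heart failure	CHF|heart failure	0
MD0007	Atrial fibrillation	afib	0
MD0008	Myocardial infarction	heart attack	0
MD0009	Cellulitis		0
MD0010	Sepsis		0
MD0011	Urinary tract infection	UTI	0
MD0012	Hepatitis C	hep C	0
MD0013	Cirrhosis		0
MD0014	Pancreatitis		0
MD0015	Gastritis		0
MD0016	Anemia		0
MD0017	Hyperlipidemia	high cholesterol	0
MD0018	Hypothyroidism		0
MD0019	Chronic kidney disease	CKD	0
MD0020	Acute kidney injury	AKI	0
MD0021	Seizure disorder	epilepsy	0
MD0022	Migraine		0
MD0023	Stroke	CVA	0
MD0024	Depression	major depressive disorder	0
MD0025	Anxiety	generalized anxiety disorder	0
MD0026	Bipolar disorder		0
MD0027	Schizophrenia		0
MD0028	Post-traumatic stress disorder	PTSD	0
MD0029	Opioid use disorder	OUD	0
MD0030	Stimulant use disorder		0
MD0031	Alcohol use disorder	AUD	0
MD0032	Tobacco use	smoking	0
MD0033	Cannabis use		0
MD0034	Overdose	drug overdose	0
MD0035	Withdrawal syndrome	withdrawal	0
MD0036	Naloxone administration		0
MD0037	Methadone maintenance		0
MD0038	Buprenorphine therapy		0
MD0039	Abscess		0
MD0040	Endocarditis		0
MD0041	Osteomyelitis		0
MD0042	Fracture		0
MD0043	Laceration		0
MD0044	Contusion		0
MD0045	Concussion		0
MD0046	Back pain	low back pain	0
MD0047	Chest pain		0
MD0048	Abdominal pain		0
MD0049	Headache		0
MD0050	Dizziness		0
MD0051	Syncope	fainting	0
MD0052	Nausea		0
MD0053	Vomiting		0
MD0054	Diarrhea		0
MD0055	Constipation		0
MD0056	Dehydration		0
MD0057	Malnutrition		0
MD0058	Obesity		0
MD0059	Insomnia		0
MD0060	Fatigue		0
MD0061	Fever		0
MD0062	Cough		0
MD0063	Dyspnea	shortness of breath	0
MD0064	Edema	swelling	0
MD0065	Rash		0
MD0066	Pruritus	itching	0
MD0067	Conjunctivitis		0
MD0068	Otitis media		0
MD0069	Pharyngitis	sore throat	0
MD0070	Sinusitis		0
MD0071	Bronchitis		0
MD0072	Influenza	flu	0
MD0073	COVID-19	coronavirus infection	0
MD0074	Tuberculosis	TB	0
MD0075	HIV infection	HIV	0
MD0076	Syphilis		0
MD0077	Gonorrhea		0
MD0078	Chlamydia infection		0
MD0079	Pregnancy		0
MD0080	Hyperglycemia		0
MD0081	Hypoglycemia		0
MD0082	Hyperkalemia		0
MD0083	Hyponatremia		0
MD0084	Tachycardia		0
MD0085	Bradycardia		0
MD0086	Hypotension		0
MD0087	Delirium		0
MD0088	Dementia		0
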