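concept_id	category	preferred_term	synonyms
SCT:3006004	medical_problem	disturbance of consciousness	disturbance of consciousness|impaired consciousness
SCT:42842009	medical_problem	cardiac murmur	cardiac murmur|heart murmur
RID3277	medical_problem	ventricular septal defect	ventricular septal defect|VSD
SYN:0101	medical_problem	atrial septal defect	atrial septal defect|ASD
SYN:0102	medical_problem	patent ductus arteriosus	patent ductus arteriosus|PDA
SYN:0103	medical_problem	cyanosis	cyanosis|bluish discoloration|紫绀
SYN:0104	medical_problem	dyspnea	dyspnea|shortness of breath|labored breathing
SYN:0105	medical_problem	fever	fever|pyrexia|发热
SYN:0106	medical_problem	cough	cough|coughing|咳嗽
SYN:0107	medical_problem	feeding difficulty	feeding difficulty|poor feeding
SYN:0108	medical_problem	wheezing	wheezing|wheeze
SYN:0109	medical_problem	pulmonary consolidation	pulmonary consolidation|lung consolidation
SYN:0110	medical_problem	pleural effusion	pleural effusion
SYN:0111	medical_problem	pneumonia	pneumonia|lung infection
SYN:0201	test	echocardiography	echocardiography|cardiac ultrasound
SYN:0202	test	chest radiograph	chest radiograph|chest x-ray
SYN:0301	treatment	antibiotic therapy	antibiotic therapy|antibiotics
SYN:0302	treatment	surgical repair	surgical repair|operative repair
SYN:0401	body_structure	interventricular septum	interventricular septum|ventricular septum
SYN:0402	body_structure	left ventricle	left ventricle
SYN:0403	body_structure	right lung	right lung
SCT:246116008	observable	lesion size	lesion size|defect size
SYN:0501	observable	body temperature	body temperature|temperature
SYN:0502	observable	respiratory rate	respiratory rate|breathing rate
SYN:0503	observable	ejection fraction	ejection fraction|EF
SYN:0601	qualifier	mild	mild
SYN:0602	qualifier	severe	severe
SYN:0603	qualifier	moderate	moderate
SYN:0701	value	numeric value	numeric value|measured value
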