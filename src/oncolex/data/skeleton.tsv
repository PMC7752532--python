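concept_id	parent_id	preferred_label	term_type	surface_form
cancer_type		cancer type	preferred	cancer type
cancer_type		cancer type	heteronym	agseong
prevention		prevention	preferred	prevention
diagnosis		diagnosis	preferred	diagnosis
diagnosis		diagnosis	abbreviation	jaegeom
diagnosis		diagnosis	synonym	jaegeomsa
diagnosis		diagnosis	abbreviation	chompa
diagnosis		diagnosis	synonym	cho-eumpa
treatment		treatment	preferred	treatment
treatment		treatment	abbreviation	holmon
treatment		treatment	synonym	holeumon
prognosis		prognosis	preferred	prognosis
risk_factor		risk factor	preferred	risk factor
symptom		symptom	preferred	symptom
dealing_with_cancer		dealing with cancer	preferred	dealing with cancer
emotion		emotion	preferred	emotion
colon_cancer	cancer_type	colon cancer	preferred	colon cancer
colon_cancer	cancer_type	colon cancer	synonym	colorectal cancer
colon_cancer	cancer_type	colon cancer	synonym	daejang-am
breast_cancer	cancer_type	breast cancer	preferred	breast cancer
breast_cancer	cancer_type	breast cancer	synonym	yubang-am
stomach_cancer	cancer_type	stomach cancer	preferred	stomach cancer
stomach_cancer	cancer_type	stomach cancer	synonym	gastric cancer
stomach_cancer	cancer_type	stomach cancer	synonym	wi-am
cervical_cancer	cancer_type	cervical cancer	preferred	cervical cancer
cervical_cancer	cancer_type	cervical cancer	synonym	jagung-am
lung_cancer	cancer_type	lung cancer	preferred	lung cancer
lung_cancer	cancer_type	lung cancer	synonym	pye-am
liver_cancer	cancer_type	liver cancer	preferred	liver cancer
liver_cancer	cancer_type	liver cancer	synonym	gan-am
pancreatic_cancer	cancer_type	pancreatic cancer	preferred	pancreatic cancer
pancreatic_cancer	cancer_type	pancreatic cancer	synonym	chwejang-am
prostate_cancer	cancer_type	prostate cancer	preferred	prostate cancer
prostate_cancer	cancer_type	prostate cancer	synonym	jeonribseon-am
brain_tumor	cancer_type	brain tumor	preferred	brain tumor
brain_tumor	cancer_type	brain tumor	synonym	noejong-yang
leukemia	cancer_type	leukemia	preferred	leukemia
leukemia	cancer_type	leukemia	synonym	baekhyeolbyeong
thyroid_cancer	cancer_type	thyroid cancer	preferred	thyroid cancer
thyroid_cancer	cancer_type	thyroid cancer	synonym	gabsangseon-am
rf_health_condition	risk_factor	health condition	preferred	health condition
rf_health_condition	risk_factor	health condition	synonym	related disease
rf_health_condition	risk_factor	health condition	synonym	health status
rf_demographic	risk_factor	demographic risk factor	preferred	demographic risk factor
rf_gender	rf_demographic	gender	preferred	gender
rf_age	rf_demographic	age	preferred	age
rf_lifestyle	risk_factor	lifestyle risk factor	preferred	lifestyle risk factor
rf_lifestyle	risk_factor	lifestyle risk factor	synonym	lifestyle
rf_dietary	rf_lifestyle	dietary risk factor	preferred	dietary risk factor
rf_dietary	rf_lifestyle	dietary risk factor	synonym	dietary habit
rf_obesity	rf_lifestyle	obesity	preferred	obesity
rf_obesity	rf_lifestyle	obesity	synonym	overweight
rf_tobacco	rf_lifestyle	tobacco	preferred	tobacco
rf_tobacco	rf_lifestyle	tobacco	synonym	smoking
rf_environmental	risk_factor	environmental risk factor	preferred	environmental risk factor
rf_chemical	rf_environmental	chemical risk factor	preferred	chemical risk factor
rf_chemical	rf_environmental	chemical risk factor	synonym	carcinogenic chemical
rf_infectious_agent	rf_environmental	infectious agent	preferred	infectious agent
rf_infectious_agent	rf_environmental	infectious agent	synonym	infection
rf_hereditary	risk_factor	hereditary risk factor	preferred	hereditary risk factor
rf_hereditary	risk_factor	hereditary risk factor	synonym	family history
sym_digestive	symptom	digestive symptom	preferred	digestive symptom
sym_digestive	symptom	digestive symptom	synonym	indigestion
sym_digestive	symptom	digestive symptom	synonym	stomachache
sym_psychological	symptom	psychological symptom	preferred	psychological symptom
sym_psychological	symptom	psychological symptom	synonym	insomnia
sym_neurological	symptom	neurological symptom	preferred	neurological symptom
sym_neurological	symptom	neurological symptom	synonym	headache
sym_metabolic	symptom	metabolic symptom	preferred	metabolic symptom
sym_metabolic	symptom	metabolic symptom	synonym	weight loss
sym_sexual_reproductive	symptom	sexual and reproductive symptom	preferred	sexual and reproductive symptom
sym_sexual_reproductive	symptom	sexual and reproductive symptom	synonym	menstrual change
dwc_daily_life	dealing_with_cancer	daily life	preferred	daily life
dwc_diet	dwc_daily_life	diet	preferred	diet
dwc_diet	dwc_daily_life	diet	synonym	food
dwc_diet	dwc_daily_life	diet	synonym	nutrition
dwc_diet	dwc_daily_life	diet	synonym	protein
dwc_diet	dwc_daily_life	diet	synonym	fruit
dwc_diet	dwc_daily_life	diet	synonym	vitamin
dwc_diet	dwc_daily_life	diet	synonym	meal
dwc_diet	dwc_daily_life	diet	synonym	vegetable
dwc_exercise	dwc_daily_life	exercise	preferred	exercise
dwc_exercise	dwc_daily_life	exercise	synonym	workout
dwc_leisure	dealing_with_cancer	leisure	preferred	leisure
dwc_sex_life	dwc_leisure	sex life	preferred	sex life
dwc_travel	dwc_leisure	travel	preferred	travel
dwc_travel	dwc_leisure	travel	synonym	trip
dwc_driving	dwc_leisure	driving	preferred	driving
dwc_support_group	dealing_with_cancer	support group	preferred	support group
dwc_support_group	dealing_with_cancer	support group	synonym	support community
tx_unspecified	treatment	unspecified treatment	preferred	unspecified treatment
tx_unspecified	treatment	unspecified treatment	synonym	therapy
tx_surgery	treatment	surgery	preferred	surgery
tx_surgery	treatment	surgery	synonym	operation
tx_chemotherapy	treatment	chemotherapy	preferred	chemotherapy
tx_chemotherapy	treatment	chemotherapy	abbreviation	chemo
px_recurrence	prognosis	recurrence	preferred	recurrence
px_recurrence	prognosis	recurrence	synonym	relapse
px_cure	prognosis	cure	preferred	cure
px_cure	prognosis	cure	synonym	complete cure
px_cure	prognosis	cure	heteronym	jol-eob
emo_overwhelmed	emotion	overwhelmed	preferred	overwhelmed
emo_denial	emotion	denial	preferred	denial
emo_anger	emotion	anger	preferred	anger
emo_fear_anxiety	emotion	fear and anxiety	preferred	fear and anxiety
emo_fear_anxiety	emotion	fear and anxiety	synonym	fear
emo_fear_anxiety	emotion	fear and anxiety	synonym	anxiety
emo_fear_anxiety	emotion	fear and anxiety	synonym	worry
emo_sadness_depression	emotion	sadness and depression	preferred	sadness and depression
emo_sadness_depression	emotion	sadness and depression	synonym	sadness
emo_sadness_depression	emotion	sadness and depression	synonym	depression
emo_guilt	emotion	guilt	preferred	guilt
emo_loneliness	emotion	loneliness	preferred	loneliness
emo_hope	emotion	hope	preferred	hope
emo_gratitude	emotion	gratitude	preferred	gratitude
emo_gratitude	emotion	gratitude	synonym	thankful
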