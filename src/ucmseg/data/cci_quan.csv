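# Charlson Comorbidity Index: Quan et al. ICD-10 coding algorithm with the
# classic weights (1/2/3/6). Prefixes uppercase, undotted; replaceable file.
prefix,weight,category
B18,1,mild_liver
B20,6,aids
B21,6,aids
B22,6,aids
B24,6,aids
C00,2,malignancy
C01,2,malignancy
C02,2,malignancy
C03,2,malignancy
C04,2,malignancy
C05,2,malignancy
C06,2,malignancy
C07,2,malignancy
C08,2,malignancy
C09,2,malignancy
C10,2,malignancy
C11,2,malignancy
C12,2,malignancy
C13,2,malignancy
C14,2,malignancy
C15,2,malignancy
C16,2,malignancy
C17,2,malignancy
C18,2,malignancy
C19,2,malignancy
C20,2,malignancy
C21,2,malignancy
C22,2,malignancy
C23,2,malignancy
C24,2,malignancy
C25,2,malignancy
C26,2,malignancy
C30,2,malignancy
C31,2,malignancy
C32,2,malignancy
C33,2,malignancy
C34,2,malignancy
C37,2,malignancy
C38,2,malignancy
C39,2,malignancy
C40,2,malignancy
C41,2,malignancy
C43,2,malignancy
C45,2,malignancy
C46,2,malignancy
C47,2,malignancy
C48,2,malignancy
C49,2,malignancy
C50,2,malignancy
C51,2,malignancy
C52,2,malignancy
C53,2,malignancy
C54,2,malignancy
C55,2,malignancy
C56,2,malignancy
C57,2,malignancy
C58,2,malignancy
C60,2,malignancy
C61,2,malignancy
C62,2,malignancy
C63,2,malignancy
C64,2,malignancy
C65,2,malignancy
C66,2,malignancy
C67,2,malignancy
C68,2,malignancy
C69,2,malignancy
C70,2,malignancy
C71,2,malignancy
C72,2,malignancy
C73,2,malignancy
C74,2,malignancy
C75,2,malignancy
C76,2,malignancy
C77,6,metastatic
C78,6,metastatic
C79,6,metastatic
C80,6,metastatic
C81,2,malignancy
C82,2,malignancy
C83,2,malignancy
C84,2,malignancy
C85,2,malignancy
C88,2,malignancy
C90,2,malignancy
C91,2,malignancy
C92,2,malignancy
C93,2,malignancy
C94,2,malignancy
C95,2,malignancy
C96,2,malignancy
C97,2,malignancy
E100,1,diabetes_uncomplicated
E101,1,diabetes_uncomplicated
E102,2,diabetes_complicated
E103,2,diabetes_complicated
E104,2,diabetes_complicated
E105,2,diabetes_complicated
E106,1,diabetes_uncomplicated
E107,2,diabetes_complicated
E108,1,diabetes_uncomplicated
E109,1,diabetes_uncomplicated
E110,1,diabetes_uncomplicated
E111,1,diabetes_uncomplicated
E112,2,diabetes_complicated
E113,2,diabetes_complicated
E114,2,diabetes_complicated
E115,2,diabetes_complicated
E116,1,diabetes_uncomplicated
E117,2,diabetes_complicated
E118,1,diabetes_uncomplicated
E119,1,diabetes_uncomplicated
E120,1,diabetes_uncomplicated
E121,1,diabetes_uncomplicated
E122,2,diabetes_complicated
E123,2,diabetes_complicated
E124,2,diabetes_complicated
E125,2,diabetes_complicated
E126,1,diabetes_uncomplicated
E127,2,diabetes_complicated
E128,1,diabetes_uncomplicated
E129,1,diabetes_uncomplicated
E130,1,diabetes_uncomplicated
E131,1,diabetes_uncomplicated
E132,2,diabetes_complicated
E133,2,diabetes_complicated
E134,2,diabetes_complicated
E135,2,diabetes_complicated
E136,1,diabetes_uncomplicated
E137,2,diabetes_complicated
E138,1,diabetes_uncomplicated
E139,1,diabetes_uncomplicated
E140,1,diabetes_uncomplicated
E141,1,diabetes_uncomplicated
E142,2,diabetes_complicated
E143,2,diabetes_complicated
E144,2,diabetes_complicated
E145,2,diabetes_complicated
E146,1,diabetes_uncomplicated
E147,2,diabetes_complicated
E148,1,diabetes_uncomplicated
E149,1,diabetes_uncomplicated
F00,1,dementia
F01,1,dementia
F02,1,dementia
F03,1,dementia
F051,1,dementia
G041,2,hemiplegia
G114,2,hemiplegia
G30,1,dementia
G311,1,dementia
G45,1,cerebrovascular
G46,1,cerebrovascular
G801,2,hemiplegia
G802,2,hemiplegia
G81,2,hemiplegia
G82,2,hemiplegia
G830,2,hemiplegia
G831,2,hemiplegia
G832,2,hemiplegia
G833,2,hemiplegia
G834,2,hemiplegia
G839,2,hemiplegia
H340,1,cerebrovascular
I099,1,congestive_heart_failure
I110,1,congestive_heart_failure
I120,2,renal
I130,1,congestive_heart_failure
I131,2,renal
I132,1,congestive_heart_failure
I21,1,myocardial_infarction
I22,1,myocardial_infarction
I252,1,myocardial_infarction
I255,1,congestive_heart_failure
I278,1,chronic_pulmonary
I279,1,chronic_pulmonary
I420,1,congestive_heart_failure
I425,1,congestive_heart_failure
I426,1,congestive_heart_failure
I427,1,congestive_heart_failure
I428,1,congestive_heart_failure
I429,1,congestive_heart_failure
I43,1,congestive_heart_failure
I50,1,congestive_heart_failure
I60,1,cerebrovascular
I61,1,cerebrovascular
I62,1,cerebrovascular
I63,1,cerebrovascular
I64,1,cerebrovascular
I65,1,cerebrovascular
I66,1,cerebrovascular
I67,1,cerebrovascular
I68,1,cerebrovascular
I69,1,cerebrovascular
I70,1,peripheral_vascular
I71,1,peripheral_vascular
I731,1,peripheral_vascular
I738,1,peripheral_vascular
I739,1,peripheral_vascular
I771,1,peripheral_vascular
I790,1,peripheral_vascular
I792,1,peripheral_vascular
I850,3,severe_liver
I859,3,severe_liver
I864,3,severe_liver
I982,3,severe_liver
J40,1,chronic_pulmonary
J41,1,chronic_pulmonary
J42,1,chronic_pulmonary
J43,1,chronic_pulmonary
J44,1,chronic_pulmonary
J45,1,chronic_pulmonary
J46,1,chronic_pulmonary
J47,1,chronic_pulmonary
J60,1,chronic_pulmonary
J61,1,chronic_pulmonary
J62,1,chronic_pulmonary
J63,1,chronic_pulmonary
J64,1,chronic_pulmonary
J65,1,chronic_pulmonary
J66,1,chronic_pulmonary
J67,1,chronic_pulmonary
J684,1,chronic_pulmonary
J701,1,chronic_pulmonary
J703,1,chronic_pulmonary
K25,1,peptic_ulcer
K26,1,peptic_ulcer
K27,1,peptic_ulcer
K28,1,peptic_ulcer
K551,1,peripheral_vascular
K558,1,peripheral_vascular
K559,1,peripheral_vascular
K700,1,mild_liver
K701,1,mild_liver
K702,1,mild_liver
K703,1,mild_liver
K704,3,severe_liver
K709,1,mild_liver
K711,3,severe_liver
K713,1,mild_liver
K714,1,mild_liver
K715,1,mild_liver
K717,1,mild_liver
K721,3,severe_liver
K729,3,severe_liver
K73,1,mild_liver
K74,1,mild_liver
K760,1,mild_liver
K762,1,mild_liver
K763,1,mild_liver
K764,1,mild_liver
K765,3,severe_liver
K766,3,severe_liver
K767,3,severe_liver
K768,1,mild_liver
K769,1,mild_liver
M05,1,rheumatic
M06,1,rheumatic
M315,1,rheumatic
M32,1,rheumatic
M33,1,rheumatic
M34,1,rheumatic
M351,1,rheumatic
M353,1,rheumatic
M360,1,rheumatic
N032,2,renal
N033,2,renal
N034,2,renal
N035,2,renal
N036,2,renal
N037,2,renal
N052,2,renal
N053,2,renal
N054,2,renal
N055,2,renal
N056,2,renal
N057,2,renal
N18,2,renal
N19,2,renal
N250,2,renal
P290,1,congestive_heart_failure
Z490,2,renal
Z491,2,renal
Z492,2,renal
Z940,2,renal
Z944,1,mild_liver
Z958,1,peripheral_vascular
Z959,1,peripheral_vascular
Z992,2,renal
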