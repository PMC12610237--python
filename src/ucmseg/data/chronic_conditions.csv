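# Provisional chronic-condition registry (38 entries). The governing programme's
# official chronic-disease list is not public; these condition classes and ICD-10
# prefixes are a clinically plausible stand-in and are meant to be replaced by a
# site-specific file with the same schema. Prefixes are uppercase and undotted.
condition_id,name,icd10_prefixes,advanced_marker_prefixes,cci_weight
diabetes_t2,Type 2 diabetes mellitus,E11,E112;E115;E117,1
diabetes_t1,Type 1 diabetes mellitus,E10,E102;E105;E107,1
hypertension,Hypertensive disease,I10;I11;I12;I13,I11;I12;I13,
hyperlipidaemia,Disorders of lipoprotein metabolism,E78,,
ischaemic_heart,Ischaemic heart disease,I20;I21;I22;I24;I25,I21;I22,1
heart_failure,Heart failure,I50,,1
atrial_fibrillation,Atrial fibrillation and flutter,I48,,
cerebrovascular,Cerebrovascular disease,I60;I61;I63;I64;I69,I69,1
peripheral_vascular,Peripheral vascular disease,I70;I73,I702,1
copd,Chronic obstructive pulmonary disease,J44,J440;J441,1
asthma,Asthma,J45;J46,J46,1
chronic_kidney,Chronic kidney disease,N18,N184;N185,2
chronic_liver,Chronic liver disease and cirrhosis,K70;K71;K73;K74;K76,K704;K711;K765;K766,1
chronic_hepatitis,Chronic viral hepatitis,B18,,1
malignancy,Malignant neoplasms (major sites),C16;C18;C22;C25;C34;C50;C53;C56;C61;C73;C85;C90;C91;C92,C77;C78;C79;C80,2
dementia,Dementia and Alzheimer disease,G30;G31,,1
parkinsons,Parkinson disease,G20,,
epilepsy,Epilepsy,G40;G41,G41,
osteoarthritis,Osteoarthritis,M15;M16;M17;M19,,
rheumatoid_arthritis,Rheumatoid arthritis,M05;M06,,1
osteoporosis,Osteoporosis,M80;M81,M80,
gout,Gout,M10,,
thyroid_disorder,Thyroid disorders,E03;E05,,
chronic_anaemia,Chronic anaemias,D50;D51;D64,,
peptic_ulcer,Peptic ulcer disease,K25;K26;K27,,1
inflammatory_bowel,Inflammatory bowel disease,K50;K51,,
psoriasis,Psoriasis,L40,L405,
glaucoma,Glaucoma,H40,,
cataract,Cataract,H25;H26,,
hearing_loss,Chronic hearing loss,H90;H91,,
prostatic_hyperplasia,Benign prostatic hyperplasia,N40,,
bronchiectasis,Bronchiectasis,J47,,
sleep_apnoea,Obstructive sleep apnoea,G473,,
obesity,Obesity,E66,,
tb_sequelae,Sequelae of tuberculosis,B90,,
hiv,HIV disease,B20;B21;B22;B24,,6
spondylosis,Spondylosis and chronic back disease,M47;M48,,
valvular_heart,Nonrheumatic valvular heart disease,I34;I35;I36,,
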