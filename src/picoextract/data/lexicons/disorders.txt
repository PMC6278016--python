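# Disorder terms (diseases, syndromes, injuries, abnormalities).
diabetes
hypertension
hypotension
asthma
cancer
carcinoma
tumor
tumour
melanoma
leukemia
lymphoma
stroke
depression
anxiety
obesity
arthritis
osteoarthritis
fibromyalgia
migraine
headache
epilepsy
seizure
seizures
copd
emphysema
bronchitis
pneumonia
influenza
sepsis
infection
infections
fracture
fractures
osteoporosis
anemia
anaemia
glaucoma
cataract
insomnia
apnea
apnoea
dementia
alzheimer
parkinson
schizophrenia
psychosis
bipolar
autism
eczema
psoriasis
dermatitis
hepatitis
cirrhosis
pancreatitis
colitis
ulcer
ulcers
gastritis
reflux
nephropathy
neuropathy
retinopathy
spasticity
sclerosis
palsy
dystrophy
thrombosis
embolism
aneurysm
arrhythmia
fibrillation
angina
ischemia
ischaemia
hyperlipidemia
hypercholesterolemia
hypothyroidism
hyperthyroidism
allergy
allergies
rhinitis
sinusitis
tuberculosis
malaria
hiv
aids
obstruction
stenosis
prolapse
hernia
incontinence
dysfunction
disorder
disorders
syndrome
disease
diseases
illness
morbidity
comorbidity
breast cancer
heart failure
myocardial infarction
low back pain
multiple sclerosis
spinal cord injury
brain injury
sudden cardiac death
familial aggregation
chronic pain
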