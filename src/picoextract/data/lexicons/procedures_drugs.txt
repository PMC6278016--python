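# Intervention terms (procedures, chemicals & drugs, devices, therapies).
aspirin
ibuprofen
paracetamol
acetaminophen
metformin
insulin
statin
statins
atorvastatin
simvastatin
warfarin
heparin
morphine
codeine
tramadol
amoxicillin
penicillin
antibiotic
antibiotics
antidepressant
antidepressants
sertraline
fluoxetine
lithium
corticosteroid
corticosteroids
prednisone
dexamethasone
salbutamol
albuterol
tizanidine
baclofen
gabapentin
pregabalin
placebo
vaccine
vaccines
vaccination
immunization
chemotherapy
radiotherapy
radiation
immunotherapy
surgery
surgical
resection
transplantation
transplant
dialysis
laparoscopy
laparoscopic
endoscopy
arthroscopy
angioplasty
stent
stenting
bypass
catheter
catheterization
ablation
vertebroplasty
kyphoplasty
defibrillator
pacemaker
implant
implantable
infusion
injection
injections
dose
dosage
mg
acupuncture
physiotherapy
rehabilitation
massage
counseling
counselling
psychotherapy
therapy
therapies
treatment
treatments
intervention
interventions
regimen
supplementation
supplement
supplements
exercise
training
anesthesia
anaesthesia
analgesia
analgesic
sedation
screening
administration
administered
medication
medications
drug
drugs
tizanidine hydrochloride
local anesthesia
back-muscle-training
peritoneal dialysis
hormone replacement
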