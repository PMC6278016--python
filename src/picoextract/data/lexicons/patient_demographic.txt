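# Age / race / gender / population keywords (demographic cues).
patient
patients
woman
women
man
men
child
children
infant
infants
newborn
newborns
neonate
neonates
toddler
toddlers
adolescent
adolescents
teenager
teenagers
adult
adults
elderly
senior
seniors
age
aged
ages
ageing
year-old
years-old
male
males
female
females
gender
sex
race
racial
ethnicity
ethnic
caucasian
hispanic
asian
african-american
pregnant
pregnancy
mother
mothers
father
fathers
participant
participants
subject
subjects
volunteer
volunteers
individual
individuals
resident
residents
inhabitant
inhabitants
population
populations
cohort
cohorts
veteran
veterans
smoker
smokers
nonsmoker
nonsmokers
diabetic
diabetics
survivor
survivors
inpatient
inpatients
outpatient
outpatients
enrollee
enrollees
person
persons
people
worker
workers
nurse-led group
middle-aged
octogenarian
octogenarians
nonagenarian
infancy
childhood
adulthood
postmenopausal
premenopausal
geriatric
pediatric
paediatric
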