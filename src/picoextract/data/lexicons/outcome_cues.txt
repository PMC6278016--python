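# Outcome cue terms (endpoints, effect vocabulary, measurement words).
outcome
outcomes
mortality
survival
death
deaths
improvement
improvements
improved
improve
reduction
reductions
reduced
decrease
decreased
increase
increased
efficacy
effectiveness
effective
benefit
benefits
beneficial
response
responses
remission
relapse
recurrence
recovery
resolution
relief
cure
cured
prevention
prevented
incidence
prevalence
rate
rates
ratio
risk
risks
hazard
odds
score
scores
scale
endpoint
endpoints
significant
significantly
nonsignificant
association
associated
correlation
correlated
difference
differences
change
changes
effect
effects
adverse
complication
complications
toxicity
tolerability
safety
failure
success
successful
prolongation
prolonged
shortened
duration
frequency
severity
symptom
symptoms
symptomatic
asymptomatic
progression
progression-free
readmission
hospitalization
hospitalisation
discharge
function
functional
disability
wellbeing
satisfaction
accuracy
accurate
sensitivity
specificity
improvement rate
quality of life
pain relief
adverse events
side effects
confidence interval
follow-up
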