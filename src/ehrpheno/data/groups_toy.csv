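phewas,group
anxiety_disorder,psychiatric
depression,psychiatric
adhd,psychiatric
ocd,psychiatric
mood_disorder,psychiatric
oppositional_disorder,psychiatric
separation_anxiety,psychiatric
speech_disorder,developmental
learning_disorder,developmental
coordination_disorder,developmental
developmental_delay,developmental
mixed_dev_disorder,developmental
milestone_delay,developmental
congenital_anomaly,developmental
epilepsy,seizures
epilepsy_nos,seizures
partial_epilepsy,seizures
generalized_epilepsy,seizures
convulsions,seizures
febrile_seizure,seizures
myoclonus,seizures
infantile_spasms,seizures
hearing_loss,auditory
otitis_media,auditory
tinnitus,auditory
constipation,gi
gerd,gi
ibd,gi
septal_defect,cardiac
arrhythmia,cardiac
murmur,cardiac
asthma,other
eczema,other
obesity,other
anemia,other
sleep_apnea,other
uri,other
viral_infection,other
diarrhea,other
enuresis,other
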