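icd9,phewas
300.00,anxiety_disorder
300.02,anxiety_disorder
311,depression
296.20,depression
314.00,adhd
314.01,adhd
300.3,ocd
312.39,ocd
296.90,mood_disorder
296.99,mood_disorder
313.81,oppositional_disorder
312.9,oppositional_disorder
309.21,separation_anxiety
309.28,separation_anxiety
315.39,speech_disorder
315.31,speech_disorder
315.00,learning_disorder
315.2,learning_disorder
315.4,coordination_disorder
781.3,coordination_disorder
315.9,developmental_delay
783.40,developmental_delay
315.8,mixed_dev_disorder
799.89,mixed_dev_disorder
783.42,milestone_delay
783.41,milestone_delay
748.3,congenital_anomaly
759.9,congenital_anomaly
345.0,epilepsy
345.1,epilepsy
345.9,epilepsy_nos
345.91,epilepsy_nos
345.4,partial_epilepsy
345.5,partial_epilepsy
345.2,generalized_epilepsy
345.3,generalized_epilepsy
780.39,convulsions
779.0,convulsions
780.31,febrile_seizure
780.32,febrile_seizure
333.2,myoclonus
345.6,infantile_spasms
389.9,hearing_loss
382.9,otitis_media
388.30,tinnitus
564.00,constipation
530.81,gerd
555.9,ibd
745.4,septal_defect
427.9,arrhythmia
785.2,murmur
493.90,asthma
691.8,eczema
278.00,obesity
285.9,anemia
327.23,sleep_apnea
465.9,uri
079.99,viral_infection
787.91,diarrhea
788.30,enuresis
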