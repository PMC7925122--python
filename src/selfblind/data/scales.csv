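scale_id,name,n_items,item_min,item_max,direction,outcome_class
rpwb,Ryff psychological well-being,42,0,6,higher_better,accumulative
cams,Cognitive and affective mindfulness scale,12,1,4,higher_better,accumulative
swl,Satisfaction with life scale,5,1,7,higher_better,accumulative
gpts,Green paranoid thought scales,32,1,5,lower_better,accumulative
b5_neuroticism,Big five: neuroticism,10,1,5,lower_better,accumulative
b5_extraversion,Big five: extraversion,10,1,5,higher_better,accumulative
b5_openness,Big five: openness,10,1,5,higher_better,accumulative
b5_agreeableness,Big five: agreeableness,10,1,5,higher_better,accumulative
b5_conscientiousness,Big five: conscientiousness,10,1,5,higher_better,accumulative
panas,Positive and negative affect schedule (net affect),10,-4,4,higher_better,acute
vas_intensity,Drug intensity VAS,1,0,100,higher_better,acute
vas_mood,Mood VAS,1,0,100,higher_better,acute
vas_energy,Energy VAS,1,0,100,higher_better,acute
vas_creativity,Creativity VAS,1,0,100,higher_better,acute
vas_focus,Focus VAS,1,0,100,higher_better,acute
vas_temper,Temper VAS,1,0,100,lower_better,acute
wemwbs,Warwick-Edinburgh mental well-being scale,14,1,5,higher_better,post_acute
qids,Quick inventory of depressive symptomatology,16,0,3,lower_better,post_acute
stait,Spielberger state-trait anxiety inventory (trait),20,1,4,lower_better,post_acute
scs,Social connectedness scale,20,1,6,higher_better,post_acute
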