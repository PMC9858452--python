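sample_id,clinical_gi
sim01,13.779267265347155
sim02,8.413448599854629
sim03,11.12460998060227
sim04,11.880808821417402
sim05,15.679969014708433
sim06,14.636873099127557
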