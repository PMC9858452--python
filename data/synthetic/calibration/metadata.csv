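sample_id,clinical_gi
sim01,21.820993900026853
sim02,8.307801673789083
sim03,11.8538116901209
sim04,8.687638171878497
sim05,20.894927777805666
sim06,21.548855757165118
sim07,15.652381007620495
sim08,9.984375875092255
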