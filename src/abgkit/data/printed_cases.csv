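case_id,ph,paco2,hco3,sbe,ag,na,cl,alb
lit-01,7.39,39,22,,19,,,
lit-02,7.41,41,24,,19,,,
lit-03,7.36,22,11,,25,,,
lit-04,7.27,44,19,,16,,,
lit-05,7.6,45,51,,14,,,
lit-06,7.42,59,36,,7,,,
lit-07,7.47,23,16,,44,,,
lit-08,7.01,26,6,,43,,,
lit-09,7.06,28,8,,10,,,23
survey-01,7.419,20,12.5,-10.79,18.5,,,40
survey-02,7.4,40,23.95,-0.4,19,,,40
survey-03,7.423,19,12,-11.2,34,,,40
survey-04,7.068,61,17,-11.44,29,,,41
survey-05,7.331,31.3,16,-8.75,10.5,,,28
survey-06,7.438,38,18,-5.42,17,,,46
survey-07,7.638,28,29,7.55,10,,,37
survey-08,7.522,27,21.4,-1.11,11,,,43
survey-09,7.042,82,21,-8.09,8,,,39
survey-10,7.308,52,25.2,-0.52,9.6,,,38
worked-1,7.4,40,24,0,11,140,105,40
worked-2,7.6,45,51,,14,,,
worked-3,7.06,28,8,,10,,,23
appcmp-elevated,7.4,40,24,,,145,100,40
appcmp-normal,7.4,40,24,,,140,105,40
fourway-discordant,7.05,15,4,-24,29,,,20
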