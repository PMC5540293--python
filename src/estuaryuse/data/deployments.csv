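year,tag_no,tag_model,deployment_date,longevity_days,sex,length_cm
2002,10927,ST16,13 July,21,Fc,320
2003,10899,ST16,5 August,83,M,370
2003,10926,ST16,4 August,112,Fc,375
2003,10971,ST16,30 July,107,M,405
2003,10972,ST16,3 August,117,Fc,344
2004,10978,ST16,24 July,224,M,410
2004,10979,ST16,24 July,268,M,400
2004,10980,ST16,25 July,231,Fc,340
2004,40622,ST16,26 July,71,Fc,408
2004,40623,ST16,27 July,201,M,409
2005,10970,Splash,23 July,37,M,330
2005,40153,Splash,30 July,50,M,310
2005,57600,Splash,30 July,213,M,265
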