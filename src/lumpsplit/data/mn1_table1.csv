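feature,affected_1,total_1,affected_2,total_2,printed_p,verified
RES (rhombencephalosynapsis),11,15,0,2,0.1103,True
Midface hypoplasia,27,36,0,8,0.0001,True
Hypertelorism,34,36,1,8,<0.0001,True
Skull shape anomalies,29,38,2,9,0.0042,True
Upper helix dysplasia,31,39,1,8,0.0007,True
Downslanting palpebral fissures,25,32,3,8,0.0386,True
Intellectual disability,28,28,1,10,<0.0001,True
Expressive speech delay,39,39,8,10,0.0383,True
Only non-verbal communication,11,21,0,7,1,False
Hypotonia,32,34,3,9,0.0003,True
Motor delay,40,42,1,10,<0.0001,True
Hearing loss (all),28,35,10,12,1,True
Conductive hearing loss,10,35,10,12,0.0017,True
Sensorineural hearing loss,6,35,0,12,1,False
Mixed hearing loss,3,35,0,12,0.5597,True
Unspecified hearing loss,9,35,0,12,0.087,True
Cleft palate,5,38,4,11,0.1786,True
High arched palate,25,38,2,11,0.0139,False
Dental issues,17,25,0,6,0.0041,True
Feeding difficulties,24,38,6,11,0.7292,True
Obstructive sleep apnoea,3,9,1,3,1,True
Cardiovascular anomalies,18,33,1,9,0.0268,True
Spinal anomalies,13,17,1,4,0.0877,True
Ophthalmological anomalies,23,33,1,9,0.0025,True
Seizures,6,32,0,9,0.309,True
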