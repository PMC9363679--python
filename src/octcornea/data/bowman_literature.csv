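method,study,mean_um,sd_um,range_lo_um,range_hi_um,repeatability_um,this_study
IVCM (9),Li et al. 1997,16.6,1.1,,,2.3,False
SR (PS) OCT (8.7),Beer et al. 2018 / Pircher et al. 2020,16,2,,,0.3,False
HR OCT (4.2),Shousha et al. 2014,15,1,,,,False
HR OCT (4.2),Eleiwa et al. 2020,,,14,21,1.1,False
HR OCT (4.2),Hu et al. 2021,17.5,2.0,,,,False
HR OCT (4.2),Li et al. 2021,18.0,1.6,,,,False
HR OCT (4.2),Tao et al. 2011 / Lian et al. 2013,17.7,1.6,,,,False
HR OCT (4.2),Xu et al. 2016,,,,,1.3,False
HR OCT (4.2),Xu et al. 2015,,,,,0.5,False
UHR OCT (1.8),Schmoll et al. 2012,18.7,2.5,,,,False
UHR OCT (1.5),Yadav et al. 2012,16.7,2.6,,,,False
UHR OCT (2.4),This work,16.6,1.5,,,0.3,True
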