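species,source,index,low,high,n
M. aurascens,kim2011,BM,5.70,7.10,10
M. aurascens,kim2011,FL,34.71,38.21,10
M. aurascens,kim2011,LHB,42.64,46.40,10
M. aurascens,kim2011,TBL,16.22,18.04,10
M. aurascens,kim2011,TL,41.03,45.26,10
M. aurascens,kim2011,EL,13.06,14.98,10
M. aurascens,kim2011,TRL,7.64,8.88,10
M. aurascens,kim2011,LHF,6.42,7.68,10
M. aurascens,oh2013,FL,33.80,37.30,7
M. aurascens,oh2013,LHB,40.80,48.00,7
M. aurascens,oh2013,TBL,15.10,17.47,7
M. aurascens,oh2013,TL,36.00,42.00,7
M. aurascens,oh2013,EL,11.00,15.00,7
M. aurascens,oh2013,TRL,6.30,9.00,7
M. aurascens,oh2013,LHF,7.00,10.00,7
M. davidii,you2021,BM,4.50,5.00,3
M. davidii,you2021,FL,34.00,34.54,3
M. davidii,you2021,LHB,38.00,41.00,3
M. davidii,you2021,TBL,15.00,15.11,3
M. davidii,you2021,TL,31.00,35.00,3
M. davidii,you2021,EL,11.00,15.00,3
M. davidii,you2021,EW,5.51,5.51,1
M. davidii,you2021,TRL,5.09,5.09,1
M. davidii,you2021,LHF,7.62,9.50,3
M. davidii,you2021,McIII,31.94,31.94,1
M. davidii,you2021,III1,12.02,12.02,1
M. davidii,you2021,III2,9.06,9.06,1
M. davidii,you2021,McIV,30.08,30.08,1
M. davidii,you2021,McV,32.67,32.67,1
M. davidii,you2021,V1,8.37,8.37,1
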