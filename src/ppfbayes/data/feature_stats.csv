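feature,min,max,mean,std,missing
Age,46,80,66.46,7.56,0
FVC%,23,107,71.66,17.62,1
FEV1%,23,112,75.58,19.32,3
DLCO,30,122,57.51,19.08,4
DLCO/VA,50,167,100.67,26.05,9
Macro%,19,93,73.95,18.43,0
Neu%,0,74,12.71,16.16,1
Lin%,2,28,9.38,6.01,0
miR-21,0.07,3.41,0.81,0.95,0
miR-92a,0.02,3.31,0.5,0.64,0
KL-6,0.0,56.87,11.23,14.76,5
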