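polymer,shape,size_um,midpoint_paf_m3_day_per_kg,endpoint_pdf_m2_yr_per_kg,source
PCL,sphere,5000,5.01E+07,1.36E+03,canonical
PCL,sphere,1000,1.34E+07,3.64E+02,canonical
PCL,sphere,100,1.38E+06,3.77E+01,canonical
PCL,sphere,10,9.55E+04,2.60E+00,canonical
PCL,sphere,1,3.24E+03,8.83E-02,canonical
PCL,fiber,5000,6.09E+07,1.66E+03,canonical
PCL,fiber,1000,1.73E+07,4.72E+02,canonical
PCL,fiber,100,1.87E+06,5.08E+01,canonical
PCL,fiber,10,1.39E+05,3.77E+00,canonical
PCL,fiber,1,5.08E+03,1.38E-01,canonical
PCL,film,5000,7.80E+07,2.12E+03,canonical
PCL,film,1000,2.46E+07,6.70E+02,canonical
PCL,film,100,2.83E+06,7.69E+01,canonical
PCL,film,10,2.29E+05,6.23E+00,canonical
PCL,film,1,9.50E+03,2.58E-01,canonical
PLA,sphere,5000,1.84E+08,5.01E+03,canonical
PLA,sphere,1000,1.25E+08,3.39E+03,canonical
PLA,sphere,100,2.87E+07,7.81E+02,canonical
PLA,sphere,10,3.29E+06,8.94E+01,canonical
PLA,sphere,1,2.79E+05,7.59E+00,canonical
PLA,fiber,5000,1.90E+08,5.17E+03,canonical
PLA,fiber,1000,1.38E+08,3.76E+03,canonical
PLA,fiber,100,3.64E+07,9.91E+02,canonical
PLA,fiber,10,4.38E+06,1.19E+02,canonical
PLA,fiber,1,3.89E+05,1.06E+01,canonical
PLA,film,5000,1.97E+08,5.35E+03,canonical
PLA,film,1000,1.56E+08,4.23E+03,canonical
PLA,film,100,4.98E+07,1.36E+03,canonical
PLA,film,10,6.53E+06,1.78E+02,canonical
PLA,film,1,6.13E+05,1.67E+01,canonical
PBSA,sphere,5000,1.56E+08,4.25E+03,canonical
PBSA,sphere,1000,8.10E+07,2.20E+03,canonical
PBSA,sphere,100,1.31E+07,3.57E+02,canonical
PBSA,sphere,10,1.34E+06,3.65E+01,canonical
PBSA,sphere,1,9.44E+04,2.57E+00,canonical
PBSA,fiber,5000,1.66E+08,4.53E+03,canonical
PBSA,fiber,1000,9.50E+07,2.58E+03,canonical
PBSA,fiber,100,1.71E+07,4.65E+02,canonical
PBSA,fiber,10,1.81E+06,4.92E+01,canonical
PBSA,fiber,1,1.37E+05,3.72E+00,canonical
PBSA,film,5000,1.78E+08,4.85E+03,canonical
PBSA,film,1000,1.15E+08,3.13E+03,canonical
PBSA,film,100,2.45E+07,6.67E+02,canonical
PBSA,film,10,2.73E+06,7.44E+01,canonical
PBSA,film,1,2.25E+05,6.13E+00,canonical
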