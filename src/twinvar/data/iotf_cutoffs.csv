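sex,age_years,cutoff_overweight,cutoff_obesity
M,2.0,18.41,20.09
M,2.5,18.13,19.80
M,3.0,17.89,19.57
M,3.5,17.69,19.39
M,4.0,17.55,19.29
M,4.5,17.47,19.26
M,5.0,17.42,19.30
M,5.5,17.45,19.47
M,6.0,17.55,19.78
M,6.5,17.71,20.23
M,7.0,17.92,20.63
M,7.5,18.16,21.09
M,8.0,18.44,21.60
M,8.5,18.76,22.17
M,9.0,19.10,22.77
M,9.5,19.46,23.39
M,10.0,19.84,24.00
M,10.5,20.20,24.57
M,11.0,20.55,25.10
M,11.5,20.89,25.58
M,12.0,21.22,26.02
M,12.5,21.56,26.43
M,13.0,21.91,26.84
M,13.5,22.27,27.25
M,14.0,22.62,27.63
M,14.5,22.96,27.98
M,15.0,23.29,28.30
M,15.5,23.60,28.60
M,16.0,23.90,28.88
M,16.5,24.19,29.14
M,17.0,24.46,29.41
M,17.5,24.73,29.70
F,2.0,18.02,19.81
F,2.5,17.76,19.55
F,3.0,17.56,19.36
F,3.5,17.40,19.23
F,4.0,17.28,19.15
F,4.5,17.19,19.12
F,5.0,17.15,19.17
F,5.5,17.20,19.34
F,6.0,17.34,19.65
F,6.5,17.53,20.08
F,7.0,17.75,20.51
F,7.5,18.03,21.01
F,8.0,18.35,21.57
F,8.5,18.69,22.18
F,9.0,19.07,22.81
F,9.5,19.45,23.46
F,10.0,19.86,24.11
F,10.5,20.29,24.77
F,11.0,20.74,25.42
F,11.5,21.20,26.05
F,12.0,21.68,26.67
F,12.5,22.14,27.24
F,13.0,22.58,27.76
F,13.5,22.98,28.20
F,14.0,23.34,28.57
F,14.5,23.66,28.87
F,15.0,23.94,29.11
F,15.5,24.17,29.29
F,16.0,24.37,29.43
F,16.5,24.54,29.56
F,17.0,24.70,29.69
F,17.5,24.85,29.84
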