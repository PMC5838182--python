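province,female_before,male_before,total_before,female_after,male_after,total_after
South khorasan,0.49,0.44,0.47,1.18,1.06,1.12
Razavi khorasan,0.95,2.19,1.57,0.39,0.89,0.64
Tehran,2.06,2.4,2.23,1.96,2.28,2.12
Markazi,0.4,0.24,0.32,0.82,0.49,0.66
Sistan,0.47,0.78,0.63,1.43,2.37,1.90
Qom,0.46,0.49,0.48,1.01,1.08,1.05
Ghazvin,0.27,0.36,0.32,0.57,0.76,0.67
Khozestan,4.53,5.65,5.09,3.98,4.96,4.47
Ilam,0.65,0.91,0.78,1.85,2.60,2.23
Bushehr,1.27,0.36,0.82,4.93,1.40,3.16
Golestan,0.44,0.87,0.66,0.77,1.52,1.14
Mazandaran,0.65,1.43,1.04,0.50,1.10,0.80
North khorasan,0.82,0.89,0.86,1.81,1.96,1.89
Chaharmahal,0.98,1.04,1.01,1.57,1.67,1.62
Isfahan,0.71,0.94,0.83,0.45,0.59,0.52
Kohgilouye,1.08,1.99,1.54,1.77,3.26,2.51
Hormozgan,0.2,0.82,0.51,0.87,3.58,2.23
Fars,2.09,2.33,2.21,1.48,1.65,1.56
Ardebil,1.16,3.23,2.20,1.40,3.90,2.65
East azarbaijan,0.84,1.1,0.97,0.53,0.69,0.61
West azarbaijan,0.15,0.9,0.53,0.24,1.45,0.84
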