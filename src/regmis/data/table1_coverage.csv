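province,coverage_percent
South khorasan,41.40
Razavi khorasan,143.74
Tehran,155.63
Markazi,69.60
Sistan,18.44
Qom,53.90
Ghazvin,66.30
Khozestan,101.19
Ilam,39.40
Bushehr,25.00
Golestan,50.80
Mazandaran,338.45
North khorasan,34.80
Chaharmahal,37.00
Isfahan,106.98
Kohgilouye,25.10
Hormozgan,19.00
Fars,127.65
Ardebil,63.00
East azarbaijan,123.60
West azarbaijan,69.00
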