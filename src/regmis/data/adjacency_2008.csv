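province_a,province_b
Tehran,Qom
Tehran,Markazi
Tehran,Ghazvin
Tehran,Mazandaran
Qom,Markazi
Qom,Isfahan
Markazi,Ghazvin
Markazi,Isfahan
Ghazvin,Mazandaran
Mazandaran,Golestan
Golestan,North khorasan
North khorasan,Razavi khorasan
Razavi khorasan,South khorasan
Razavi khorasan,Sistan
South khorasan,Sistan
Sistan,Hormozgan
Hormozgan,Fars
Hormozgan,Bushehr
Fars,Bushehr
Fars,Isfahan
Fars,Kohgilouye
Kohgilouye,Isfahan
Kohgilouye,Khozestan
Kohgilouye,Bushehr
Kohgilouye,Chaharmahal
Chaharmahal,Isfahan
Chaharmahal,Khozestan
Bushehr,Khozestan
Khozestan,Ilam
Ardebil,East azarbaijan
West azarbaijan,East azarbaijan
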