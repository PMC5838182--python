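sender,receiver
Qom,Tehran
Markazi,Tehran
Ghazvin,Tehran
Chaharmahal,Isfahan
Kohgilouye,Isfahan
Golestan,Mazandaran
Bushehr,Khozestan
Ilam,Khozestan
Hormozgan,Fars
Ardebil,East azarbaijan
West azarbaijan,East azarbaijan
North khorasan,Razavi khorasan
South khorasan,Razavi khorasan
Sistan,Razavi khorasan
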