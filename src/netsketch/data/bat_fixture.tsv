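BatA	BatB
BatA	BatC
BatA	BatD
BatA	BatE
BatA	Hypo
BatA	MoxR
BatA	P03
BatA	P13
BatA	P17
BatA	P19
BatA	P20
BatA	P22
BatA	P27
BatA	P30
BatA	P33
BatA	P35
BatA	P36
BatA	P46
BatA	P49
BatA	P51
BatA	P56
BatA	P63
BatA	P66
BatA	P69
BatA	PA3071
BatB	BatC
BatB	BatD
BatB	BatE
BatB	Hypo
BatB	MoxR
BatB	P03
BatB	P05
BatB	P06
BatB	P08
BatB	P10
BatB	P14
BatB	P15
BatB	P19
BatB	P22
BatB	P33
BatB	P35
BatB	P40
BatB	P48
BatB	P51
BatB	P63
BatB	P64
BatB	P67
BatB	P69
BatB	P70
BatB	PA3071
BatC	BatD
BatC	BatE
BatC	Hypo
BatC	MoxR
BatC	P03
BatC	P06
BatC	P07
BatC	P14
BatC	P18
BatC	P21
BatC	P22
BatC	P23
BatC	P36
BatC	P45
BatC	P63
BatC	P66
BatC	P67
BatC	PA3071
BatD	BatE
BatD	Hypo
BatD	MoxR
BatD	P01
BatD	P02
BatD	P03
BatD	P04
BatD	P05
BatD	P06
BatD	P07
BatD	P10
BatD	P12
BatD	P13
BatD	P14
BatD	P15
BatD	P16
BatD	P17
BatD	P18
BatD	P19
BatD	P20
BatD	P21
BatD	P22
BatD	P25
BatD	P29
BatD	P30
BatD	P31
BatD	P33
BatD	P35
BatD	P36
BatD	P37
BatD	P39
BatD	P41
BatD	P42
BatD	P44
BatD	P45
BatD	P47
BatD	P49
BatD	P50
BatD	P51
BatD	P52
BatD	P55
BatD	P57
BatD	P58
BatD	P59
BatD	P60
BatD	P63
BatD	P66
BatD	P67
BatD	P68
BatD	P69
BatD	P70
BatD	PA3071
BatE	Hypo
BatE	MoxR
BatE	P01
BatE	P03
BatE	P07
BatE	P13
BatE	P14
BatE	P15
BatE	P18
BatE	P19
BatE	P20
BatE	P22
BatE	P30
BatE	P34
BatE	P35
BatE	P38
BatE	P40
BatE	P43
BatE	P49
BatE	P51
BatE	P57
BatE	P61
BatE	P63
BatE	P65
BatE	P66
BatE	P67
BatE	P68
BatE	P69
BatE	PA3071
Hypo	MoxR
Hypo	P03
Hypo	P04
Hypo	P05
Hypo	P06
Hypo	P07
Hypo	P08
Hypo	P09
Hypo	P10
Hypo	P11
Hypo	P12
Hypo	P13
Hypo	P15
Hypo	P18
Hypo	P19
Hypo	P21
Hypo	P22
Hypo	P23
Hypo	P24
Hypo	P26
Hypo	P27
Hypo	P28
Hypo	P32
Hypo	P33
Hypo	P34
Hypo	P37
Hypo	P51
Hypo	P52
Hypo	P53
Hypo	P54
Hypo	P60
Hypo	P62
Hypo	P63
Hypo	P64
Hypo	P65
Hypo	P66
Hypo	P67
Hypo	P68
Hypo	P69
Hypo	PA3071
MoxR	P03
MoxR	P15
MoxR	P17
MoxR	P20
MoxR	P23
MoxR	P29
MoxR	P32
MoxR	P35
MoxR	P57
MoxR	P66
MoxR	P67
MoxR	P69
MoxR	PA3071
P03	PA3071
P09	PA3071
P11	PA3071
P15	P52
P17	PA3071
P19	P63
P19	P67
P19	PA3071
P22	P33
P22	PA3071
P33	PA3071
P61	PA3071
P63	PA3071
P67	PA3071
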