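subject,group,dprime,criterion
RIOT4,acquired,0.47,-0.23
BIOT2,acquired,0.47,0.29
LIOT2,acquired,-0.69,-0.50
BATOT2,acquired,1.33,0.62
RAT2,acquired,0.51,0.00
RAT3,acquired,0.71,-0.35
BAT1,acquired,0.14,0.77
BAT2,acquired,1.23,-0.09
DP014,developmental,1.03,0.77
DP016,developmental,0.92,-0.71
DP021,developmental,2.69,-0.06
DP024,developmental,1.31,0.19
DP033,developmental,2.12,0.22
DP035,developmental,1.09,0.29
DP038,developmental,2.35,0.47
DP044,developmental,0.40,0.05
DP039,developmental,2.28,0.14
DP202,developmental,2.05,-1.03
C1,control,3.40,-0.05
C2,control,3.40,-0.05
C3,control,3.03,-0.23
C4,control,2.82,0.23
C5,control,2.59,-0.45
C6,control,2.46,0.05
C7,control,2.28,-0.61
C8,control,2.11,0.59
C9,control,2.11,0.59
C10,control,1.86,0.35
C11,control,1.84,-0.08
C12,control,1.70,-0.33
C13,control,1.68,0.00
C14,control,1.39,0.95
C15,control,1.03,0.77
C16,control,0.99,-0.50
C17,control,0.99,0.35
C18,control,0.78,0.14
C19,control,0.18,-0.62
C20,control,-0.10,-0.20
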