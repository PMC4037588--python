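# Small molecules (<= 8 atoms) used as exhaustive-enumeration fixtures for the
# isotope-pattern engine.  name<TAB>formula as element:count pairs separated by commas
H2	H:2
O2	O:2
N2	N:2
CO	C:1,O:1
CO2	C:1,O:2
H2O	H:2,O:1
NH3	N:1,H:3
CH4	C:1,H:4
H2S	H:2,S:1
SO2	S:1,O:2
SO3	S:1,O:3
C2H2	C:2,H:2
HCN	H:1,C:1,N:1
N2O	N:2,O:1
NO2	N:1,O:2
CH2O	C:1,H:2,O:1
CH4O	C:1,H:4,O:1
C2H4	C:2,H:4
C2H6	C:2,H:6
CS2	C:1,S:2
COS	C:1,O:1,S:1
CH4S	C:1,H:4,S:1
C3H4	C:3,H:4
N2H4	N:2,H:4
H2O2	H:2,O:2
C2N2	C:2,N:2
C2H3N	C:2,H:3,N:1
HNO3	H:1,N:1,O:3
H2SO4	H:2,S:1,O:4
C2H2O2	C:2,H:2,O:2
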