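# Stable-isotope masses (Da) and natural abundances (fraction of element).
# NIST/CODATA reference values.  One row per isotope: element<TAB>mass<TAB>abundance
# The pseudo-element "proton" carries the mass of H+ for m/z arithmetic.
H	1.00782503207	0.999885
H	2.01410177785	0.000115
C	12.0	0.9893
C	13.00335483507	0.0107
N	14.00307400443	0.99636
N	15.00010889888	0.00364
O	15.99491461956	0.99757
O	16.99913175650	0.00038
O	17.99915961286	0.00205
S	31.9720711744	0.9499
S	32.9714589098	0.0075
S	33.9678670040	0.0425
S	35.9670807100	0.0001
proton	1.007276466621	1.0
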