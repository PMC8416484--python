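# Default pKa values for ionizable groups (v1), conventional biochemistry set.
# <residue or terminus><whitespace><pKa><whitespace><polarity>
D 3.65 acidic
E 4.25 acidic
C 8.30 acidic
Y 10.07 acidic
H 6.00 basic
K 10.53 basic
R 12.48 basic
NTERM 8.00 basic
CTERM 3.10 acidic
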