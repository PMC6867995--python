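# AT-rich organellar-like dinucleotide composition (arbitrary total;
# only the relative frequencies matter for the Markov null generator).
# The table is Euler-balanced: in- and out-counts agree for every base.
AA 120
AU 105
AC 52
AG 58
UA 105
UU 115
UC 58
UG 55
CA 52
CU 58
CC 28
CG 28
GA 58
GU 55
GC 28
GG 30
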