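# Reduced nearest-neighbor stacking table, kcal/mol at 37 C.
# Columns: outer pair (5'X..Y3' -> "XY"), inner stacked pair, dG.
# Watson-Crick terms follow standard nearest-neighbor magnitudes;
# G.U wobble terms use flat representative values.
AU AU -0.93
UA UA -0.93
AU UA -1.10
UA AU -1.33
CG UA -2.08
AU GC -2.08
CG AU -2.11
UA GC -2.11
GC UA -2.24
AU CG -2.24
GC AU -2.35
UA CG -2.35
CG GC -2.36
GC GC -3.26
CG CG -3.26
GC CG -3.42
AU GU -0.80
AU UG -0.80
UA GU -0.80
UA UG -0.80
GC GU -0.80
GC UG -0.80
CG GU -0.80
CG UG -0.80
GU AU -0.80
GU UA -0.80
GU GC -0.80
GU CG -0.80
UG AU -0.80
UG UA -0.80
UG GC -0.80
UG CG -0.80
GU GU -0.50
GU UG -0.50
UG GU -0.50
UG UG -0.50
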