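variable_id,weight
Sever,0.081
Urg,0.076
Jclin,0.066
Tsuen,0.063
Tlist,0.062
Pmcx,0.055
Dest,0.054
Com,0.053
Lfam,0.053
Hanor,0.052
Opat,0.047
Diag,0.046
Olim,0.045
Ncuid,0.043
Rcuid,0.043
Dolor,0.040
Dtrab,0.038
Acc,0.033
Dtras,0.028
Ccrit,0.023
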