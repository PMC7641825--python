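dimension,level,decrement
mo,1,0.000
mo,2,0.110
mo,3,0.145
mo,4,0.180
mo,5,0.205
sc,1,0.000
sc,2,0.111
sc,3,0.145
sc,4,0.183
sc,5,0.210
ua,1,0.000
ua,2,0.105
ua,3,0.140
ua,4,0.173
ua,5,0.195
pd,1,0.000
pd,2,0.115
pd,3,0.155
pd,4,0.200
pd,5,0.225
ad,1,0.000
ad,2,0.112
ad,3,0.148
ad,4,0.186
ad,5,0.190
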