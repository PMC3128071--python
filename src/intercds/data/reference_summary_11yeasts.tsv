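# Published summary statistics of inter-CDS length distributions in 11 yeast
# species: per (species, age, orientation) stratum, the mean length (bp) and
# the location of the lower limit of the distribution (bp).
#species	age	orientation	mean_bp	lower_limit_bp
sce	old	divergent	489	172
sce	old	unidirectional	412	159
sce	old	convergent	205	49
sce	young	divergent	486	27
sce	young	unidirectional	453	12
sce	young	convergent	415	19
ago	old	divergent	322	78
ago	old	unidirectional	291	63
ago	old	convergent	106	9
ago	young	divergent	531	59
ago	young	unidirectional	416	58
ago	young	convergent	227	10
cgl	old	divergent	616	206
cgl	old	unidirectional	606	242
cgl	old	convergent	248	64
cgl	young	divergent	918	178
cgl	young	unidirectional	752	189
cgl	young	convergent	354	99
kla	old	divergent	613	199
kla	old	unidirectional	513	193
kla	old	convergent	172	19
kla	young	divergent	904	186
kla	young	unidirectional	686	158
kla	young	convergent	327	29
kpo	old	divergent	853	255
kpo	old	unidirectional	725	265
kpo	old	convergent	213	40
kpo	young	divergent	1496	335
kpo	young	unidirectional	896	166
kpo	young	convergent	339	83
kth	old	divergent	427	84
kth	old	unidirectional	360	97
kth	old	convergent	103	10
kth	young	divergent	968	154
kth	young	unidirectional	788	91
kth	young	convergent	465	48
kwa	old	divergent	345	88
kwa	old	unidirectional	340	74
kwa	old	convergent	88	8
kwa	young	divergent	433	17
kwa	young	unidirectional	370	18
kwa	young	convergent	464	16
sba	old	divergent	518	173
sba	old	unidirectional	438	165
sba	old	convergent	217	52
sba	young	divergent	1194	168
sba	young	unidirectional	1071	194
sba	young	convergent	909	153
sca	old	divergent	380	122
sca	old	unidirectional	360	130
sca	old	convergent	158	43
sca	young	divergent	643	129
sca	young	unidirectional	467	118
sca	young	convergent	231	39
skl	old	divergent	412	95
skl	old	unidirectional	445	111
skl	old	convergent	155	18
skl	young	divergent	920	111
skl	young	unidirectional	745	65
skl	young	convergent	511	36
zro	old	divergent	408	100
zro	old	unidirectional	312	85
zro	old	convergent	96	9
zro	young	divergent	750	138
zro	young	unidirectional	538	95
zro	young	convergent	273	30
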