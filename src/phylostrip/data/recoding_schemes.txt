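# Amino acid recoding schemes, one group per line:
#   <scheme> <member> <member> ...     target symbol = first member
#   <scheme> ? <member> ...            members mapped to missing
dayhoff6 A G P S T
dayhoff6 D E N Q
dayhoff6 H K R
dayhoff6 F Y W
dayhoff6 I L M V
dayhoff6 C
dayhoff4 A G P S T
dayhoff4 D E N Q
dayhoff4 H K R
dayhoff4 F Y W I L M V
dayhoff4 ? C
hp A C F G I L M V W
hp D E H K N P Q R S T Y
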