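name,mole_percent
alanine,9.6
arginine,5.5
asparagine,4.5
aspartate,4.5
cysteine,1.7
glutamate,4.9
glutamine,4.9
glycine,11.5
histidine,1.8
isoleucine,5.4
leucine,8.4
lysine,6.4
methionine,2.9
phenylalanine,3.5
proline,4.1
serine,4.0
threonine,4.7
tryptophan,1.1
tyrosine,2.6
valine,7.9
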