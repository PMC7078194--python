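metabolite,formula,polarity,charge
glutamine,C5H10N2O3,positive,1
glutamate,C5H9NO4,negative,-1
aspartate,C4H7NO4,negative,-1
alpha-ketoglutarate,C5H6O5,negative,-1
fumarate,C4H4O4,negative,-1
citrate,C6H8O7,negative,-1
IMP,C10H13N4O8P,negative,-1
AMP,C10H14N5O7P,negative,-1
GMP,C10H14N5O8P,negative,-1
UMP,C9H13N2O9P,negative,-1
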