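gene,position,mutant
RT,20,K
RT,36,I
RT,89,N
RT,102,K
RT,211,K
IN,17,N
IN,32,I
IN,79,K
IN,112,N
IN,201,K
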