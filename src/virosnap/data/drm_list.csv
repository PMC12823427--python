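gene,position,mutant,drug
RT,101,E,rilpivirine
RT,101,P,rilpivirine
RT,103,N,rilpivirine
RT,103,S,rilpivirine
RT,106,A,rilpivirine
RT,108,I,rilpivirine
RT,138,A,rilpivirine
RT,138,G,rilpivirine
RT,138,K,rilpivirine
RT,138,Q,rilpivirine
RT,138,R,rilpivirine
RT,179,L,rilpivirine
RT,181,C,rilpivirine
RT,181,I,rilpivirine
RT,181,V,rilpivirine
RT,188,L,rilpivirine
RT,221,Y,rilpivirine
RT,227,C,rilpivirine
RT,230,I,rilpivirine
RT,230,L,rilpivirine
IN,66,K,cabotegravir
IN,74,M,cabotegravir
IN,92,Q,cabotegravir
IN,92,V,cabotegravir
IN,118,R,cabotegravir
IN,138,A,cabotegravir
IN,138,K,cabotegravir
IN,140,A,cabotegravir
IN,140,R,cabotegravir
IN,140,S,cabotegravir
IN,148,H,cabotegravir
IN,148,K,cabotegravir
IN,148,R,cabotegravir
IN,155,H,cabotegravir
IN,230,R,cabotegravir
IN,263,K,cabotegravir
RT,65,R,nrti
RT,184,I,nrti
RT,184,V,nrti
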