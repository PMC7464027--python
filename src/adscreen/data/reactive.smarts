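# Reactive-group substructure alerts (Oprea-style), one per line:
# <name><TAB><SMARTS>
# The flag descriptor is 1 if any pattern matches.  The list is data, not
# code: edit or extend without touching the implementation.
metal	[Li,Na,K,Rb,Cs,Be,Mg,Ca,Sr,Ba,Al,Sn,Pb,Mn,Fe,Co,Ni,Cu,Zn,Cr,Hg,Cd,Ag,Ti]
phospho	[#15]
het_het_single_bond	[NX3,OX2,SX2;!$([NX3,OX2,SX2]=*)]-[NX3,OX2,SX2;!$([NX3,OX2,SX2]=*)]
thiol	[SX2H]
acyl_halide	[CX3](=[OX1])[F,Cl,Br,I]
michael_acceptor	[CX3]=[CX3][CX3]=[OX1]
azide	[$([NX2]=[NX2+]=[NX1-]),$([NX2-][NX2+]#[NX1])]
ester	[CX3](=[OX1])[OX2][#6;!$([#6]=[#8])]
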