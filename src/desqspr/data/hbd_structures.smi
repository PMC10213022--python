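CC(O)CO	1,2-Propanediol
OCCCCO	1,4-Butanediol
CC(O)C(O)C	2,3-Butanediol
OCCOCCO	Diethylene glycol
OCc1ccco1	Furfuryl alcohol
COc1ccccc1O	Guaiacol
CC(=O)CCC(=O)O	Levulinic acid
Oc1ccccc1	Phenol
OCCOCCOCCO	Triethylene glycol
OCC(O)CO	Glycerol
OCCO	Ethylene glycol
NC(N)=O	Urea
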