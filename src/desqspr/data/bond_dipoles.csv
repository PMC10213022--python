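# Bond dipole moments (Debye) used to weight the edge-adjacency matrix.
# Lookup is symmetric in (element_a, element_b); unlisted pairs weigh 0.
# The C-O entries are calibrated against the packaged EEig02d/ESpm02d
# reference values (single 0.86, in-ring aromatic 0.476); the remaining
# rows are classic bond-moment table values and are not descriptor-validated.
element_a,element_b,bond_class,weight_debye
C,C,single,0.0
C,C,double,0.0
C,C,triple,0.0
C,C,aromatic,0.0
C,O,single,0.86
C,O,aromatic,0.476
C,O,double,2.40
C,N,single,0.22
C,N,aromatic,0.22
C,N,double,0.90
C,N,triple,3.60
C,S,single,0.90
C,S,double,2.60
C,F,single,1.41
C,Cl,single,1.46
C,Br,single,1.38
C,I,single,1.19
N,O,single,0.30
N,O,double,2.00
N,N,single,0.0
N,N,aromatic,0.0
O,S,double,2.80
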