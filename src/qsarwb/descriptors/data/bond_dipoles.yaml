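# Bond dipole moments (Debye) keyed by "El1-El2:order" with the element pair
# sorted alphabetically and order one of 1, 1.5, 2, 3. Used as the diagonal
# augmentation of the edge adjacency matrix in the dipole-weighted spectral
# moment descriptors. Values follow common literature bond-moment tables;
# this file is an editable, declared approximation of any proprietary "dm"
# weighting scheme. Homonuclear bonds carry zero dipole by symmetry.
C-C:1: 0.0
C-C:1.5: 0.0
C-C:2: 0.0
C-C:3: 0.0
C-N:1: 0.22
C-N:1.5: 0.22
C-N:2: 1.40
C-N:3: 3.60
C-O:1: 0.74
C-O:1.5: 0.74
C-O:2: 2.30
C-S:1: 0.90
C-S:1.5: 0.90
C-S:2: 2.00
C-F:1: 1.41
C-Cl:1: 1.46
C-Br:1: 1.38
C-I:1: 1.19
C-P:1: 0.80
C-B:1: 0.70
C-Si:1: 0.60
N-N:1: 0.0
N-N:1.5: 0.0
N-N:2: 0.0
N-O:1: 0.30
N-O:1.5: 0.30
N-O:2: 2.00
N-S:1: 0.50
N-S:1.5: 0.50
N-S:2: 1.00
N-P:1: 0.60
O-O:1: 0.0
O-S:1: 0.70
O-S:2: 2.80
O-P:1: 0.80
O-P:2: 2.70
S-S:1: 0.0
F-S:1: 0.80
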