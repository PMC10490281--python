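# Per-element atomic property table used for weighted topological and
# geometric descriptors. All weights are used carbon-scaled (w_i / w_C).
#
#   mass            atomic mass, amu (IUPAC 2021 standard atomic weights)
#   polarizability  static dipole polarizability, Å³ (Miller/CRC compilation)
#   vdw_radius      Bondi van der Waals radius, Å (volume = 4/3 π r³)
#
# Edit or extend to cover additional elements; unknown elements raise a
# configuration error at descriptor time.
H:  {mass: 1.008,   polarizability: 0.667, vdw_radius: 1.20}
B:  {mass: 10.811,  polarizability: 3.030, vdw_radius: 1.92}
C:  {mass: 12.011,  polarizability: 1.760, vdw_radius: 1.70}
N:  {mass: 14.007,  polarizability: 1.100, vdw_radius: 1.55}
O:  {mass: 15.999,  polarizability: 0.802, vdw_radius: 1.52}
F:  {mass: 18.998,  polarizability: 0.557, vdw_radius: 1.47}
Si: {mass: 28.086,  polarizability: 5.380, vdw_radius: 2.10}
P:  {mass: 30.974,  polarizability: 3.630, vdw_radius: 1.80}
S:  {mass: 32.06,   polarizability: 2.900, vdw_radius: 1.80}
Cl: {mass: 35.45,   polarizability: 2.180, vdw_radius: 1.75}
Br: {mass: 79.904,  polarizability: 3.050, vdw_radius: 1.85}
I:  {mass: 126.904, polarizability: 5.350, vdw_radius: 1.98}
Se: {mass: 78.971,  polarizability: 3.770, vdw_radius: 1.90}
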