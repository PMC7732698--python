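# Idealized Fv reference core for the ABangle-style measures.
# Synthetic coordinates (not derived from any published consensus set):
# eight pseudo-Calpha positions per variable domain arranged as a thin,
# oblique elliptical plate. Columns: domain(H|L) label x y z  [Angstrom].
# Labels are ordinal slots matched against vh_core_residues /
# vl_core_residues of the partition config, in order.
H 1 -8.768033 3.005129 -4.439352
H 2 -10.220127 4.286541 -0.445681
H 3 -14.595098 2.598807 4.038868
H 4 -20.189753 -0.132848 5.865861
H 5 -23.010355 -3.308284 4.577137
H 6 -22.001486 -3.983386 0.307896
H 7 -17.183289 -2.901962 -3.901082
H 8 -12.031860 0.436003 -6.003646
L 1 7.022958 -2.380135 -5.104216
L 2 4.697522 1.395910 -5.288168
L 3 0.128558 4.596288 -1.974237
L 4 -4.954638 4.818747 2.052131
L 5 -6.765842 2.509633 5.381925
L 6 -4.954638 -1.525407 5.010459
L 7 0.128558 -4.466790 2.251946
L 8 4.697522 -4.948245 -2.329840
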