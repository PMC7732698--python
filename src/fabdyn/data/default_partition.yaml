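# Template Fab domain partition (Chothia-style numbering, heavy chain H,
# light chain L). These ranges are a STARTING POINT for a standard Fab and
# must be adapted to the actual numbering of each structure; fabdyn performs
# no automatic annotation. Ranges are inclusive on both ends; insertion-coded
# residues (e.g. 100A) sort within their parent number.
#
# Keys:
#   vh / vl / ch1 / cl          the four immunoglobulin domains
#   switch_heavy / switch_light the "switch" residues bridging V and C
#   ch1_cterm_loops / cl_cterm_loops
#                               C-terminal loop sets of the constant domains,
#                               used by the C_H1-C_L interface torsion; which
#                               residues constitute these loops is a user
#                               decision and must be reviewed per structure.
#   v_pairs / c_pairs           optional Calpha residue pairings used for the
#                               pseudo-two-fold axes of the classic elbow
#                               angle (heavy residue <-> structurally
#                               equivalent light residue).
#   vh_core_residues / vl_core_residues
#                               residue numbers whose Calpha atoms are matched
#                               against the packaged idealized Fv reference
#                               core for the ABangle-style measures.
partition:
  vh: {chain: H, ranges: [[1, 113]]}
  switch_heavy: {chain: H, ranges: [[114, 118]]}
  ch1: {chain: H, ranges: [[119, 215]]}
  ch1_cterm_loops: {chain: H, ranges: [[190, 215]]}
  vl: {chain: L, ranges: [[1, 107]]}
  switch_light: {chain: L, ranges: [[108, 112]]}
  cl: {chain: L, ranges: [[113, 211]]}
  cl_cterm_loops: {chain: L, ranges: [[186, 211]]}
  v_pairs:
    - [[H, 36], [L, 35]]
    - [[H, 38], [L, 38]]
    - [[H, 46], [L, 44]]
    - [[H, 86], [L, 84]]
    - [[H, 92], [L, 88]]
    - [[H, 103], [L, 98]]
  c_pairs:
    - [[H, 124], [L, 118]]
    - [[H, 146], [L, 140]]
    - [[H, 160], [L, 154]]
    - [[H, 178], [L, 172]]
    - [[H, 196], [L, 190]]
  vh_core_residues: [36, 37, 38, 39, 45, 46, 86, 92]
  vl_core_residues: [35, 36, 37, 38, 43, 44, 84, 88]
analysis:
  temperature_k: 300.0
  equilibration_frames_discarded: 0
  histogram_bin_width_deg: 0.5
  fit_window_kbt: 2.0
  band_edges_ns: [0.1, 10.0]
  random_seed: 0
  com_weighting: mass
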