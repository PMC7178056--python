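# Demo pipeline config: a 20-residue synthetic protein with a three-ring
# ligand and planted interactions of every analysed kind.
# Run:  mdligand run --config examples/demo.yaml --out demo_out
analysis:
  burn_in: 100.0        # ps; the generated run drifts for its first 100 frames
  temperature: 310.0
  rng_seed: 0

synthetic:
  n_residues: 20
  residue_plan: [GLY, ALA, SER, ALA, ARG, ALA, GLU, ALA, PHE, ALA,
                 ALA, ALA, TRP, ALA, ALA, ALA, ASP, ALA, LYS, GLY]
  ligand_rings: 3
  n_frames: 500
  dt: 1.0
  fluct_sigma: 0.02
  drift_frames: 100
  seed: 0
  correlation_blocks:
    - {residues: [10, 11], rho: 0.9}
  planted_hbonds:
    - {donor_residue: 3, acceptor_residue: 15, fraction: 0.7}
  planted_saltbridge: {basic_residue: 4, acidic_residue: 6, distance_nm: 0.18}
  planted_stacking:
    - {protein_ring: "PHE9:ring0", ligand_ring: 0, angle_deg: 0.0,
       distance_nm: 0.42, fraction: 0.9}
  planted_contacts:
    - {residue: 14, fraction: 0.3}

options:
  energy_frame_stride: 8
  sasa_stride: 5
  rank_threshold: -1.0
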