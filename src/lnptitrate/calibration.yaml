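# Calibration constants for the synthetic-data presets.
#
# These encode the printed target statistics of the study system (a
# Comirnaty-like ALC-0315:DSPC:cholesterol:ALC-0159 membrane) so that
# closed-loop recovery tests can compare fitted parameters against the
# values the generators were built to emit.

intrinsic_pka: 9.26          # reference pKa of ALC-0315 at infinite dilution
global_apparent_pka: 4.91    # apparent pKa of aminolipids inside the patch
surface_pka_lnp: 5.47        # surface-charge-density pKa (no TNS probe)
tns_offset: 0.39             # probe-induced upward shift: 5.47 + 0.39 = 5.86
surface_n: 0.5               # anti-cooperativity at the membrane surface
deep_n: 0.8                  # cooperativity at ~1.1 nm insertion depth
deep_n_depth: -1.1           # nm (negative = inside the membrane)
local_pka_surface: 7.5       # local apparent pKa near the surface (6..8 band)
local_pka_core: 4.0          # local apparent pKa in the hydrophobic core

# Engine preset parameters for the membrane-patch generators.  The surface
# well depth is calibrated by two-dimensional quadrature of the joint
# (lambda, depth) Boltzmann measure so that the emergent global apparent
# pKa of the patch equals global_apparent_pka above (see
# scenarios.predict_global_pka).
patch:
  profile:
    surface_pka: 7.5
    core_pka: 4.0
    midpoint_depth: -0.5
    steepness: 6.0
  well_surface_kj: 11.43
  well_core_kj: 3.6
  anticoop_kj: 0.0
  depth_bounds: [-3.5, 1.0]
  # bilayer P-P distance chosen so the fivefold LNP-phase thickening gives
  # t ~ 14.2 nm and a slab-to-sphere diameter 3 t ~ 42.6 nm
  thickness_bilayer: 2.85
  mrna_strength_kj: 15.0
  mrna_depth_nm: -2.5   # insertion depth of the anionic loci (inside the core)
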