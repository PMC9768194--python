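# Simplified nearest-neighbor RNA folding parameters (kcal/mol, 37 C).
#
# This is a deliberately compact parameter set: helix stability comes from
# stacking of adjacent base pairs, destabilization from length-dependent
# loop penalties, and multiloops are scored with the usual linear model.
# Terminal mismatches, dangling ends and special hairpin sequences are not
# modeled.  Values are round-number summaries of the usual magnitude of
# nearest-neighbor parameters, not any published table.

kT: 0.616          # kcal/mol at 37 C
min_loop: 3        # minimum unpaired nt enclosed by a pair
max_interior_span: 30   # max unpaired nt per side of a bulge/internal loop

# stack[outer][inner]: outer pair (i,j) stacked on inner pair (i+1,j-1)
stack:
  CG: {CG: -3.30, GC: -3.20, GU: -2.35, UG: -2.25, AU: -2.70, UA: -2.60}
  GC: {CG: -3.20, GC: -3.10, GU: -2.25, UG: -2.15, AU: -2.60, UA: -2.50}
  GU: {CG: -2.35, GC: -2.25, GU: -1.40, UG: -1.30, AU: -1.75, UA: -1.65}
  UG: {CG: -2.25, GC: -2.15, GU: -1.30, UG: -1.20, AU: -1.65, UA: -1.55}
  AU: {CG: -2.70, GC: -2.60, GU: -1.75, UG: -1.65, AU: -2.10, UA: -2.00}
  UA: {CG: -2.60, GC: -2.50, GU: -1.65, UG: -1.55, AU: -2.00, UA: -1.90}

# loop initiation penalties by number of unpaired nt; sizes beyond the table
# are extrapolated as E(m) = E(m_max) + slope * ln(m / m_max)
hairpin_loop: {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
bulge_loop: {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
internal_loop: {2: 4.1, 3: 5.1, 4: 4.9, 5: 5.3, 6: 5.7}
extrapolation_slope: 1.08   # ~1.75 * kT

multiloop:
  initiation: 3.4     # closing a multiloop
  per_branch: 0.4     # each helix branching off (closing helix included)
  per_unpaired: 0.4   # each unpaired nt inside the multiloop
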