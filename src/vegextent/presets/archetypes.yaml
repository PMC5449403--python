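# Named synthetic-survey scenarios.
#
# Each archetype draws a species' expected stalk count per 2 x 2 m plot as
#   lambda(d) = baseline * (1 + (near_multiplier - 1) * sigma(d))
# with sigma a decreasing logistic in log distance (midpoint_m, steepness).
# Pioneers carry near_multiplier > 1 (boosted near the corridor),
# original dominants < 1 (suppressed near, recovered by d_eff),
# accompanying species a small baseline with reduced near-corridor occupancy.
#
# d_eff is the ground-truth effect extent: the distance by which every
# suppressed dominant has recovered to within a few percent of baseline.

s1_like:
  design: S1
  d_eff_m: 300
  count_dispersion: 0.2
  archetypes:
    - {name: "Pioneer grass A",    role: pioneer,           baseline: 6.0,  near_multiplier: 7.0,  midpoint_m: 60,  steepness: 3.0, cover_per_stalk: 0.35, cover_shape: 4.0, occupancy: 0.95, near_occupancy: 0.95}
    - {name: "Pioneer reed B",     role: pioneer,           baseline: 4.0,  near_multiplier: 10.0, midpoint_m: 80,  steepness: 3.0, cover_per_stalk: 0.40, cover_shape: 4.0, occupancy: 0.9,  near_occupancy: 0.95}
    - {name: "Pioneer shrub C",    role: pioneer,           baseline: 5.0,  near_multiplier: 5.0,  midpoint_m: 50,  steepness: 2.5, cover_per_stalk: 0.35, cover_shape: 4.0, occupancy: 0.9,  near_occupancy: 0.9}
    - {name: "Dominant herb D",    role: original_dominant, baseline: 25.0, near_multiplier: 0.08, midpoint_m: 150, steepness: 3.0, cover_per_stalk: 1.1, cover_shape: 4.0, occupancy: 0.95, near_occupancy: 0.6}
    - {name: "Dominant shrub E",   role: original_dominant, baseline: 20.0, near_multiplier: 0.1,  midpoint_m: 140, steepness: 3.0, cover_per_stalk: 1.3, cover_shape: 4.0, occupancy: 0.95, near_occupancy: 0.6}
    - {name: "Accompanying forb F", role: accompanying,     baseline: 2.0,  near_multiplier: 0.05, midpoint_m: 60,  steepness: 2.0, cover_per_stalk: 0.8, cover_shape: 3.0, occupancy: 0.6,  near_occupancy: 0.1}
    - {name: "Accompanying forb G", role: accompanying,     baseline: 1.8,  near_multiplier: 0.05, midpoint_m: 70,  steepness: 2.0, cover_per_stalk: 0.7, cover_shape: 3.0, occupancy: 0.6,  near_occupancy: 0.1}
    - {name: "Accompanying grass H", role: accompanying,    baseline: 2.2,  near_multiplier: 0.05, midpoint_m: 80,  steepness: 2.0, cover_per_stalk: 0.8, cover_shape: 3.0, occupancy: 0.55, near_occupancy: 0.1}

s2_like:
  design: S2
  d_eff_m: 100
  count_dispersion: 0.2
  archetypes:
    - {name: "Pioneer grass A",    role: pioneer,           baseline: 5.0,  near_multiplier: 6.0,  midpoint_m: 25,  steepness: 3.0, cover_per_stalk: 0.40, cover_shape: 4.0, occupancy: 0.95, near_occupancy: 0.95}
    - {name: "Pioneer forb B",     role: pioneer,           baseline: 4.0,  near_multiplier: 8.0,  midpoint_m: 30,  steepness: 3.0, cover_per_stalk: 0.35, cover_shape: 4.0, occupancy: 0.9,  near_occupancy: 0.95}
    - {name: "Dominant grass C",   role: original_dominant, baseline: 22.0, near_multiplier: 0.1,  midpoint_m: 50,  steepness: 3.0, cover_per_stalk: 1.1, cover_shape: 4.0, occupancy: 0.95, near_occupancy: 0.6}
    - {name: "Dominant shrub D",   role: original_dominant, baseline: 18.0, near_multiplier: 0.1,  midpoint_m: 45,  steepness: 3.0, cover_per_stalk: 1.3, cover_shape: 4.0, occupancy: 0.95, near_occupancy: 0.6}
    - {name: "Accompanying forb E", role: accompanying,     baseline: 2.0,  near_multiplier: 0.05, midpoint_m: 25,  steepness: 2.0, cover_per_stalk: 0.8, cover_shape: 3.0, occupancy: 0.6,  near_occupancy: 0.15}
    - {name: "Accompanying forb F", role: accompanying,     baseline: 1.8,  near_multiplier: 0.05, midpoint_m: 30,  steepness: 2.0, cover_per_stalk: 0.7, cover_shape: 3.0, occupancy: 0.6,  near_occupancy: 0.15}

"null":
  design: S1
  d_eff_m: null
  count_dispersion: 0.2
  archetypes:
    - {name: "Steppe grass A", role: accompanying, baseline: 12.0, near_multiplier: 1.0, midpoint_m: 100, steepness: 2.0, cover_per_stalk: 1.1, cover_shape: 4.0, occupancy: 0.95, near_occupancy: 0.95}
    - {name: "Steppe shrub B", role: accompanying, baseline: 9.0,  near_multiplier: 1.0, midpoint_m: 100, steepness: 2.0, cover_per_stalk: 1.2, cover_shape: 4.0, occupancy: 0.9,  near_occupancy: 0.9}
    - {name: "Steppe forb C",  role: accompanying, baseline: 5.0,  near_multiplier: 1.0, midpoint_m: 100, steepness: 2.0, cover_per_stalk: 0.8, cover_shape: 3.0, occupancy: 0.8,  near_occupancy: 0.8}
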