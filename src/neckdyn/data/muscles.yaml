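# Default neck-muscle bundle table: 13 muscle groups discretised into 19
# straight-line bundles, with the spring-damper globals shared by all of them.
# Units are as conventionally tabulated for this material model: lengths in mm,
# velocities in mm/s, forces in kg*mm/s^2 (= millinewtons), areas in mm^2.
schema: neckdyn-muscles-1
globals:
  sv: 1.0            # scale factor applied to vmax (dimensionless)
  fpe_scale: 0.0     # parallel-elastic force scale; 0 disables the PE element
  lmax: 0.8          # relative stretch at which the PE force reaches fmax
  ksh: 2.0           # exponential shape constant of the PE curve
  fl_width: 0.5      # half-width of the quadratic force-length bell, fraction of lo
  fv_curvature: 0.25 # Hill concentric curvature constant
  fv_plateau: 1.3    # eccentric force plateau (x isometric)
  fv_shape: 0.15     # eccentric branch shape constant
bundles:
  - {group: sternocleidomastoid, lo_mm: 180, vmax_mm_s: 1980, fmax_kg_mm_s2: 44825, pcsa_mm2: 358.6}
  - {group: longus_colli,        lo_mm: 60,  vmax_mm_s: 650,  fmax_kg_mm_s2: 25000, pcsa_mm2: 200}
  - {group: longus_colli,        lo_mm: 15,  vmax_mm_s: 165,  fmax_kg_mm_s2: 25000, pcsa_mm2: 200}
  - {group: longus_colli,        lo_mm: 40,  vmax_mm_s: 440,  fmax_kg_mm_s2: 25000, pcsa_mm2: 200}
  - {group: longus_capitis,      lo_mm: 85,  vmax_mm_s: 935,  fmax_kg_mm_s2: 50000, pcsa_mm2: 200}
  - {group: longus_capitis,      lo_mm: 55,  vmax_mm_s: 605,  fmax_kg_mm_s2: 50000, pcsa_mm2: 200}
  - {group: scalenus_anterior,   lo_mm: 110, vmax_mm_s: 1210, fmax_kg_mm_s2: 41400, pcsa_mm2: 165.6}
  - {group: scalenus_anterior,   lo_mm: 80,  vmax_mm_s: 880,  fmax_kg_mm_s2: 41400, pcsa_mm2: 165.6}
  - {group: scalenus_medius,     lo_mm: 65,  vmax_mm_s: 715,  fmax_kg_mm_s2: 10900, pcsa_mm2: 43.5}
  - {group: scalenus_posterior,  lo_mm: 60,  vmax_mm_s: 660,  fmax_kg_mm_s2: 34000, pcsa_mm2: 136}
  - {group: trapezius,           lo_mm: 160, vmax_mm_s: 1760, fmax_kg_mm_s2: 87500, pcsa_mm2: 350}
  - {group: semispinalis_capitis, lo_mm: 120, vmax_mm_s: 1320, fmax_kg_mm_s2: 37500, pcsa_mm2: 150}
  - {group: semispinalis_capitis, lo_mm: 90,  vmax_mm_s: 990,  fmax_kg_mm_s2: 37500, pcsa_mm2: 150}
  - {group: semispinalis_cervicis, lo_mm: 80, vmax_mm_s: 880,  fmax_kg_mm_s2: 17950, pcsa_mm2: 71.8}
  - {group: longissimus_capitis, lo_mm: 115, vmax_mm_s: 1265, fmax_kg_mm_s2: 20000, pcsa_mm2: 80}
  - {group: longissimus_capitis, lo_mm: 75,  vmax_mm_s: 825,  fmax_kg_mm_s2: 20000, pcsa_mm2: 80}
  - {group: longissimus_cervicis, lo_mm: 75, vmax_mm_s: 825,  fmax_kg_mm_s2: 20000, pcsa_mm2: 80}
  - {group: splenius_capitis,    lo_mm: 175, vmax_mm_s: 1925, fmax_kg_mm_s2: 18700, pcsa_mm2: 224.4}
  - {group: splenius_cervicis,   lo_mm: 110, vmax_mm_s: 1210, fmax_kg_mm_s2: 18700, pcsa_mm2: 84.7}
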