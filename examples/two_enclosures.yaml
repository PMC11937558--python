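# One herd of 8 horses tracked in a small paddock and a large field.
# Both conditions share the same roster and affinity structure (seeded by
# `seed`), so differences between the two runs reflect space, not identity.
seed: 3
output_dir: runs/two_enclosures
n_boot: 200
conditions:
  - name: paddock
    enclosure: {length_m: 30, width_m: 15, n_horses: 8, tracking_hours: 1.0}
    source:
      simulate: {duration_s: 3600, feeder: true}
  - name: field
    enclosure: {length_m: 65, width_m: 40, area_m2: 2682, n_horses: 8, tracking_hours: 1.0}
    source:
      simulate: {duration_s: 3600, feeder: false}
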