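# Device preset registry (lengths in mm, angles in degrees).
#
# Lattice pitches, wire counts and braid angles are fixed a priori at
# values representative of each device class.  Metal widths and maximum
# compaction factors were calibrated once against published single-device
# coverage on a 5.27 mm neck / 4 mm parent artery (enterprise 7.0 %,
# lvis 20.4 % -> 35.4 % compacted, pipeline 26.8 % -> 47.8 % compacted)
# with scripts/calibrate_presets.py.  Do not hand-edit the calibrated
# numbers; rerun the script instead.

enterprise:
  device_class: laser_cut
  strut_width_mm: 0.030131
  axial_pitch_mm: 1.2
  circumferential_pitch_mm: 1.2
  max_compaction: 1.0   # laser-cut cells are rigid

lvis:
  device_class: braided
  wire_diameter_mm: 0.071454
  n_wires: 16
  braid_angle_deg: 65.0
  max_compaction: 1.9558

pipeline:
  device_class: braided
  wire_diameter_mm: 0.025853
  n_wires: 48
  braid_angle_deg: 70.0
  max_compaction: 2.0120
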