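# Geometry of the hand-held camera modelled by the package defaults:
# 39 x 39 x 5 mm CZT crystal, 600 V bias, 16 x 16 anode array with
# 2.46 mm pitch and 1.86 mm pads, medium-energy collimator.
crystal:
  width_x: 39.0        # mm
  width_y: 39.0        # mm
  thickness: 5.0       # mm
  bias_voltage: 600.0  # V
  permittivity_rel: 10.9

anodes:
  n_x: 16
  n_y: 16
  pitch: 2.46          # mm
  pad_size: 1.86       # mm

collimator: MEGP       # LEHR | MEGP | OPEN, or an inline block:
# collimator:
#   name: custom
#   hole_length: 11.5
#   wall_thickness: 0.96
#   hole_width: 1.50
#   material: lead
#   hole_shape: circular
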