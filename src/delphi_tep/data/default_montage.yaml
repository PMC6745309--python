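# Default 20-electrode analysis montage for left-M1 TMS-EEG.
# Regions are grouped by role relative to the stimulated hemisphere
# (stimulation over left M1, C3 vicinity): "ipsi" = left, "contra" = right.
# positions_2d are schematic unit-disk head coordinates (x right, y front),
# used only for rendering, never for analysis.
stim_site: C3
region_groups:
  frontal:
    ipsi: [F3, F5]
    contra: [F4, F6]
  parietal:
    ipsi: [C3, C5, CP1]
    contra: [C4, C6, CP2]
  temporal:
    ipsi: [CP5, CP3, FC5]
    contra: [CP6, CP4, FC6]
  occipital:
    ipsi: [O1, PO3]
    contra: [O2, PO4]
positions_2d:
  F3: [-0.35, 0.45]
  F5: [-0.55, 0.42]
  F4: [0.35, 0.45]
  F6: [0.55, 0.42]
  C3: [-0.40, 0.00]
  C5: [-0.60, 0.00]
  CP1: [-0.20, -0.20]
  C4: [0.40, 0.00]
  C6: [0.60, 0.00]
  CP2: [0.20, -0.20]
  CP5: [-0.60, -0.25]
  CP3: [-0.40, -0.22]
  FC5: [-0.55, 0.22]
  CP6: [0.60, -0.25]
  CP4: [0.40, -0.22]
  FC6: [0.55, 0.22]
  O1: [-0.25, -0.75]
  PO3: [-0.30, -0.58]
  O2: [0.25, -0.75]
  PO4: [0.30, -0.58]
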