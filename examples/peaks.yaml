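# Apo/holo HSQC-style peak tables: combined shifts implanted at the binding
# site, with the site's apo peaks broadened (low intensity) and recovering
# to baseline upon binding.  Residues default to 25-155.
seed: 22
shifts:
  128: [0.03, 0.2]
  129: [0.10, 0.6]
  144: [0.08, 0.5]
apo_intensity:
  129: 0.2
  144: 0.25
shift_noise: 0.002
intensity_noise: 0.05
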