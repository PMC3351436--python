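# Holo relaxation data: same residues and global tumbling, exchange and
# extra flexibility at the binding site quenched by the ligand.
residues: [30, 31, 32, 33, 34, 35, 36, 37, 38, 39, 40, 41, 42, 43, 44, 45,
           46, 47, 48, 49, 50, 51, 52, 53, 54, 55, 56, 57, 58, 59, 60, 61,
           62, 63, 64, 65, 66, 67, 68, 69, 70, 120, 121, 122, 123, 124, 125,
           126, 127, 128, 129, 130, 131, 132, 133, 134, 135, 140, 141, 142,
           143, 144, 145, 146, 147, 148, 149, 150, 151, 152, 153]
s2: 0.85
tau_m: 8.0
tau_e: 50.0
field_mhz: 500.0
seed: 24
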