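# Unperturbed (apo) Gaussian-network trajectory: 131-residue folded core
# numbered 25-155, compact reference chain, 600 frames.
n_residues: 131
first_residue: 25
n_frames: 600
seed: 20
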