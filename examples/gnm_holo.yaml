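# Ligand-bound (holo) variant: contacts of the 5-residue binding site
# (128-132) stiffened 5x, contacts of the distal 4-residue region (66-69)
# softened to 0.3x - the implanted direct + allosteric perturbation.
n_residues: 131
first_residue: 25
n_frames: 600
seed: 21
perturbations:
- [[128, 129, 130, 131, 132], 5.0]
- [[66, 67, 68, 69], 0.3]
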