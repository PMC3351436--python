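# Full-pipeline configuration for the synthetic apo/holo comparison.
# Generate the referenced inputs first (paths relative to this directory):
#
#   allodyn simulate traj  --spec examples/gnm_apo.yaml   --out-prefix examples/out/apo
#   allodyn simulate traj  --spec examples/gnm_holo.yaml  --out-prefix examples/out/holo
#   allodyn simulate peaks --spec examples/peaks.yaml     --out-prefix examples/out/peaks
#   allodyn simulate relax --spec examples/relax_apo.yaml  --out-prefix examples/out/relax_apo
#   allodyn simulate relax --spec examples/relax_holo.yaml --out-prefix examples/out/relax_holo
#   allodyn run --config examples/config.yaml --out examples/out/report \
#       --annotations examples/annotations_fgf2.tsv
inputs:
  apo_trajectory: examples/out/apo.tsv
  holo_trajectory: examples/out/holo.tsv
  apo_peaks: examples/out/peaks_apo.tsv
  holo_peaks: examples/out/peaks_holo.tsv
  apo_relaxation: examples/out/relax_apo.tsv
  holo_relaxation: examples/out/relax_holo.tsv
parameters:
  range: "25:155"
  atom: CA
  cutoff: 8.0
  window: 50
  k: 1.0
  min_len: 3
  alpha: 0.154
  criterion: AIC
  consensus_min_stages: 2
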