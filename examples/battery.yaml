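# Full default-battery run from a single config:
#
#   mvpa-adapt run-plan --config examples/battery.yaml --out results/battery
#
# Or stage by stage:
#
#   mvpa-adapt simulate   --config examples/battery.yaml --out results/data
#   mvpa-adapt preprocess --in results/data --out results/samples.npz
#   mvpa-adapt decode     --samples results/samples.npz --scheme within_loocv \
#       --train-format dots --test-format dots --train-group 5yo --test-group 5yo \
#       --radius 2 --out results/maps
#   mvpa-adapt infer      --maps 'results/maps/*.nii' --mask results/data/mask.nii \
#       --voxel-p 0.005 --perms 1000 --out results/inference

simulate:
  grid_shape: [13, 13, 13]
  mask_radius_voxels: 3.0
  n_per_group: {"5yo": 10, "8yo": 10}
  formats_per_group:
    "5yo": [dots, digits, letters]
    "8yo": [dots, digits]
  seed: 11
  region_specs:
    # a format-independent quantity code in the younger group
    - center: [6, 6, 6]
      radius: 1.5
      effect_formats: [dots, digits]
      groups: ["5yo"]
      effect_size: 3.0
      shared_across_formats: true
      cross_participant_consistency: 0.9

searchlight:
  radius: 2.0

inference:
  fast: true           # 1,000 permutations; drop for the 50,000 fidelity default
  voxel_p_threshold: 0.005
  cluster_alpha: 0.05

battery:
  residualized: true
  kfold: 10
  alt_voxel_p: 0.001

seed: 0
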