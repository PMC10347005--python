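# Augmentation-size sweep on the mid-difficulty synthetic scenario:
# 6 classes x 12 trials, 7 train / 5 test per class, four classifier
# families, interpolation-extrapolation augmentation with k=3 and
# alpha ~ Uniform(-2, 3), ten trainings per cell.
dataset: overlapping
trials_per_class: 12
train_per_class: 7
test_per_class: 5
classifiers:
  - {kind: ann, nl: 3, nu: 50}
  - {kind: msvm}
  - {kind: rf, n_trees: 100}
  - {kind: pca_msvm, nv: 3}
augment: {method: interp_extrap, k: 3, c1: -2, c2: 3}
sizes: [0, 100, 500, 2000]
repeats: 10
master_seed: 0
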