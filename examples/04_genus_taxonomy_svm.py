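"""Genus identification within one growth habit by PCA + one-vs-one SVM.

Generates four spectrally distinct herb classes, preprocesses them, reduces
the concatenated fingerprint + CH-stretch regions to nine principal
components, trains the Gaussian-kernel one-vs-one ensemble on 100 score
sets per class, cross-validates, and scores the held-out test set.
"""

import numpy as np

from pollenraman.chemometrics import TrainConfig, run_taxonomy
from pollenraman.preprocess import preprocess_pipeline
from pollenraman.simulate import SpectrumDesign, generate_dataset, separable_profiles

profiles = separable_profiles(4, amplitude_delta=0.2)
design = SpectrumDesign(n_per_class=150, noise_sd=0.02, seed=4)
dataset = generate_dataset(profiles, design)
processed, _ = preprocess_pipeline(dataset)

result = run_taxonomy(processed, "herb", train_config=TrainConfig(n_train_scores=100, seed=4))

print(f"genera: {', '.join(result.genera)}")
print(f"cumulative variance of 9 PCs: {result.cumulative_variance:.2%}")
print(f"one-vs-one binary learners: {result.svm.n_learners}")
print(f"10-fold CV misclassification: {result.cv_misclassification:.2%}")
print(f"held-out test accuracy: {result.confusion.accuracy:.1%} ({result.confusion.total} spectra)")
for genus in result.confusion.labels:
    print(
        f"  {genus}: sensitivity {result.confusion.sensitivity[genus]:6.1%}, "
        f"PPV {result.confusion.positive_predictive_value[genus]:6.1%}"
    )
print("t-SNE class medians (training scores):")
for genus, median in result.embedding.class_medians.items():
    print(f"  {genus}: ({median[0]:7.2f}, {median[1]:7.2f})")
# CV misclassification estimates model performance from the training design
# alone; the test accuracy is measured on spectra the model never saw.
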