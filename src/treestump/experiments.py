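"""Reproducible method-comparison experiments on synthetic corpora.

This module wires the pieces together into the package's headline
experiment: train BoVW-SVM(lin) and HOG-SVM(RBF) on one synthetic patch
corpus, evaluate both on held-out windows cropped from freshly
generated scenes, and report precision/recall/false-acceptance plus
row-normalised confusion matrices for each.  The evaluation corpus is
deliberately class-imbalanced (about five non-trunk windows per trunk
window), mirroring the composition of real suburban imagery where
trunk-free regions vastly outnumber trunks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from treestump.bovw import BovwClassifier
from treestump.colorhog import ColorHogClassifier
from treestump.evaluation import MetricsReport, evaluate_patch_predictions
from treestump.seeds import derive_seed
from treestump.synthetic import generate_patch_dataset


@dataclass
class ComparisonResult:
    """Held-out metrics of both learning-based methods on one corpus."""

    bovw_lin: MetricsReport
    hog_rbf: MetricsReport
    n_eval_windows: int
    n_eval_scenes: int
    seed: int


def run_method_comparison(
    seed: int,
    n_train_pos: int = 300,
    n_train_neg: int = 300,
    n_eval_pos: int = 1000,
    n_eval_neg: int = 5000,
    difficulty: float = 0.0,
    patch_size: int = 64,
    k: int = 200,
    pos_per_scene: int = 5,
    neg_per_scene: int = 25,
) -> ComparisonResult:
    """Train and evaluate both learning-based detectors on one corpus.

    Training and evaluation patches come from disjoint streams of
    generated scenes (different derived seeds).  Default evaluation
    sizes -- 1000 trunk and 5000 non-trunk windows drawn from 200
    scenes -- keep a realistic 1:5 class imbalance while fitting a
    single-CPU run.
    """
    train_patches, train_labels = generate_patch_dataset(
        n_train_pos, n_train_neg, patch_size=patch_size,
        seed=derive_seed(seed, "train"), difficulty=difficulty,
        pos_per_scene=pos_per_scene, neg_per_scene=neg_per_scene,
    )
    eval_patches, eval_labels = generate_patch_dataset(
        n_eval_pos, n_eval_neg, patch_size=patch_size,
        seed=derive_seed(seed, "eval"), difficulty=difficulty,
        pos_per_scene=pos_per_scene, neg_per_scene=neg_per_scene,
    )
    n_eval_scenes = int(np.ceil(max(
        n_eval_pos / pos_per_scene if pos_per_scene else 0,
        n_eval_neg / neg_per_scene if neg_per_scene else 0,
    )))

    bovw = BovwClassifier.train(train_patches, train_labels, k=k,
                                seed=derive_seed(seed, "bovw"))
    hog = ColorHogClassifier.train(train_patches, train_labels,
                                   seed=derive_seed(seed, "hog"))

    bovw_report = evaluate_patch_predictions(eval_labels, bovw.predict(eval_patches))
    hog_report = evaluate_patch_predictions(eval_labels, hog.predict(eval_patches))
    return ComparisonResult(
        bovw_lin=bovw_report,
        hog_rbf=hog_report,
        n_eval_windows=len(eval_labels),
        n_eval_scenes=n_eval_scenes,
        seed=seed,
    )
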