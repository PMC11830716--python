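"""End-to-end experiment runner on the synthetic study design.

Streams trials through preprocessing and feature extraction (so no
more than one raw trial is in memory at a time), then for each
(feature family, state) pair: stratified 8:2 split, Fisher-LDA
reduction to 5 dimensions fitted on the training rows, FCNN training
with per-epoch test accuracy, and optionally the six baseline
classifiers on the same reduced features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import BASELINE_NAMES, baseline_compare, evaluate, split_dataset
from .fcnn import FCNNClassifier, HIDDEN_DEFAULT
from .features import FAMILIES, FeatureMatrix, extract_all
from .lda import FisherLDA
from .preprocess import analysis_slices, preprocess_trial
from .significance import band_sd_observations
from .synth import GeneratorConfig, iter_dataset


@dataclass
class ExperimentResult:
    #: family -> FeatureMatrix over all analysis slices (both states)
    features: dict[str, FeatureMatrix]
    #: band-SD observations for the significance analysis
    observations: pd.DataFrame
    #: rows: family x state x algorithm with train/test accuracy
    accuracy_table: pd.DataFrame
    #: (family, state) -> EvalReport of the FCNN
    reports: dict = field(default_factory=dict)


def extract_features(config: GeneratorConfig, families=FAMILIES,
                     collect_observations: bool = True):
    """Generate, preprocess and featurise the whole design, streaming."""
    all_slices = []
    for trial in iter_dataset(config):
        all_slices.extend(analysis_slices(preprocess_trial(trial)))
    feats = extract_all(all_slices, families)
    obs = band_sd_observations(all_slices) if collect_observations else None
    return feats, obs


def classify_family(fm: FeatureMatrix, state: str, seed: int = 0,
                    epochs: int = 50, hidden_layer_sizes=HIDDEN_DEFAULT,
                    n_components: int = 5, with_baselines: bool = False,
                    lda_fit_on_all: bool = False):
    """Split / reduce / train / evaluate one (family, state) dataset.

    ``lda_fit_on_all=True`` fits the LDA on all rows including the test
    rows before the split (optimistic; off by default).
    """
    mask = (fm.meta["state"] == state).to_numpy()
    sub = fm.subset(mask)
    tr, te = split_dataset(sub.y, ratio=0.8, seed=seed)
    lda = FisherLDA(n_components=n_components)
    if lda_fit_on_all:
        lda.fit(sub.X, sub.y)
    else:
        lda.fit(sub.X[tr], sub.y[tr])
    Ztr, Zte = lda.transform(sub.X[tr]), lda.transform(sub.X[te])
    clf = FCNNClassifier(hidden_layer_sizes=hidden_layer_sizes,
                         epochs=epochs, random_state=seed)
    clf.fit(Ztr, sub.y[tr], eval_set=(Zte, sub.y[te]))
    report = evaluate(clf, Zte, sub.y[te])
    rows = [{
        "family": fm.family, "state": state, "algorithm": "FCNN",
        "train_accuracy": float(np.mean(clf.predict(Ztr) == sub.y[tr])),
        "test_accuracy": report.accuracy,
        "best_epoch": clf.best_epoch_,
        "best_epoch_accuracy": getattr(clf, "best_eval_accuracy_", report.accuracy),
        "final_epoch_accuracy": clf.history_[-1]["eval_accuracy"],
    }]
    if with_baselines:
        Z = np.vstack([Ztr, Zte])
        yz = np.concatenate([sub.y[tr], sub.y[te]])
        base = baseline_compare(
            Z, yz, seed=seed,
            algorithms=[a for a in BASELINE_NAMES if a != "FCNN"])
        for _, r in base.iterrows():
            rows.append({"family": fm.family, "state": state,
                         "algorithm": r["algorithm"],
                         "train_accuracy": r["train_accuracy"],
                         "test_accuracy": r["test_accuracy"],
                         "best_epoch": None,
                         "best_epoch_accuracy": None,
                         "final_epoch_accuracy": None})
    return pd.DataFrame(rows), report, lda, clf


def run_experiment(n_subjects: int = 20, seed: int = 0, effect_size: float = 1.0,
                   families=FAMILIES, states=("speaking", "quiet"),
                   epochs: int = 50, hidden_layer_sizes=HIDDEN_DEFAULT,
                   with_baselines: bool = False,
                   lda_fit_on_all: bool = False) -> ExperimentResult:
    """Full pipeline on a fresh synthetic dataset."""
    config = GeneratorConfig(n_subjects=n_subjects, seed=seed,
                             effect_size=effect_size)
    feats, obs = extract_features(config, families)
    tables, reports = [], {}
    for fam in families:
        for state in states:
            tab, report, _, _ = classify_family(
                feats[fam], state, seed=seed, epochs=epochs,
                hidden_layer_sizes=hidden_layer_sizes,
                with_baselines=with_baselines,
                lda_fit_on_all=lda_fit_on_all)
            tables.append(tab)
            reports[(fam, state)] = report
    return ExperimentResult(
        features=feats,
        observations=obs,
        accuracy_table=pd.concat(tables, ignore_index=True),
        reports=reports,
    )
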