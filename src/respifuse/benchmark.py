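"""End-to-end fusion benchmark on seeded synthetic cohorts.

For each replicate cohort the pipeline runs from raw signals: DCT
denoising of the fiber waveforms, endpoint detection and splicing of the
audio, extraction of the representative blocks (9 fiber-frequency, 9
audio-rhythm, 7 leukocyte), then a 5-fold CV comparison of the fusion
methods (SCCA-LMF, plain LMF, CONCAT) under the SVS classifier.  All
label-using steps (LMF training, SMOTE, tuning) happen inside the
training split of each fold; SCCA penalties are selected by CV on the
training split.

The headline comparison is the one-sided sign test on per-replicate
pooled CV AUC: SCCA-LMF vs CONCAT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from . import reference_sets as refs
from .audio import AudioFeatureRegistry, extract_audio_features
from .classify import (SvsConfig, SVSClassifier, _default_learners,
                       cross_validate_svs, smote_oversample)
from .cohort import Cohort, CohortSpec, generate_cohort
from .errors import ConfigurationError
from .fiber import extract_fiber_features
from .fusion import LowRankFusion, SparseCCA, concat_fuse, select_scca_penalties
from .metrics import roc_curve
from .preprocess import (DctDenoiseConfig, EndpointConfig, dct_denoise,
                         detect_endpoints, splice_segments)
from .records import FeatureTable

FFR = list(refs.REPRESENTATIVE_FIBER_FREQUENCY)
ARH = list(refs.REPRESENTATIVE_AUDIO_RHYTHM)
LMLC = list(refs.REPRESENTATIVE_BLOOD_LEUKOCYTE)


def extract_representative_blocks(cohort: Cohort,
                                  denoise: bool = True,
                                  endpointing: bool = True
                                  ) -> dict[str, FeatureTable]:
    """Raw cohort -> the three representative feature blocks.

    The audio path uses a prosody-only registry because every audio-rhythm
    representative feature is a prosody HSF; the fiber path computes the
    full 79-dimension vector and keeps the frequency representatives.
    """
    labels = cohort.labels
    fiber_vectors = []
    for rec in cohort.fiber:
        if denoise:
            cfg = DctDenoiseConfig.from_cutoff_hz(len(rec), rec.rate)
            rec = dct_denoise(rec, cfg)
        fiber_vectors.append(extract_fiber_features(rec))
    fiber_table = FeatureTable.from_vectors(fiber_vectors, labels)

    reg = AudioFeatureRegistry.prosody_only()
    audio_vectors = []
    for rec in cohort.audio:
        if endpointing:
            segs = detect_endpoints(rec, EndpointConfig.for_rate(rec.rate))
            spliced = splice_segments(rec, segs)
            frame_len, _ = reg.frame_lengths(rec.rate)
            if spliced.samples.size >= frame_len:
                rec = spliced
        vec = extract_audio_features(rec, reg)
        vec.subject_id = rec.subject_id
        audio_vectors.append(vec)
    audio_table = FeatureTable.from_vectors(audio_vectors, labels)

    blood_table = cohort.blood.to_feature_table()
    return {"ffr": fiber_table.select(FFR),
            "arh": audio_table.select(ARH),
            "lmlc": blood_table.select(LMLC)}


@dataclass(frozen=True)
class FusionSettings:
    n_components: int = 2
    rank: int = 4
    h_dim: int = 8
    lmf_steps: int = 2000
    lmf_lr: float = 0.01
    seed: int = 0
    select_penalties: bool = True
    lam1: float = 0.0
    lam2: float = 0.0


def make_feature_builder(method: str, settings: FusionSettings):
    """Per-fold feature construction for :func:`cross_validate_svs`.

    Both train and test tables must contain the FFr + ARh + LMLC columns;
    the builder returns the fused train/test tables for ``method``.
    """
    if method == "concat":
        return None  # the combined table already is the early fusion

    def build(train: FeatureTable, test: FeatureTable):
        lmlc_tr, lmlc_te = train.select(LMLC), test.select(LMLC)
        if method == "scca-lmf":
            X_tr, Y_tr = train.select(FFR), train.select(ARH)
            if settings.select_penalties:
                lam1, lam2 = select_scca_penalties(X_tr, Y_tr,
                                                   seed=settings.seed)
            else:
                lam1, lam2 = settings.lam1, settings.lam2
            scca = SparseCCA(lam1=lam1, lam2=lam2,
                             n_components=settings.n_components)
            scca.fit(X_tr, Y_tr)
            cflc_tr = scca.transform(X_tr, Y_tr)
            cflc_te = scca.transform(test.select(FFR), test.select(ARH))
        elif method == "lmf":
            # plain LMF: the raw respiratory block stands in for CFLC
            cflc_tr = train.select(FFR + ARH)
            cflc_te = test.select(FFR + ARH)
        else:
            raise ConfigurationError(f"unknown fusion method {method!r}")
        lmf = LowRankFusion(rank=settings.rank, h_dim=settings.h_dim,
                            learning_rate=settings.lmf_lr,
                            n_steps=settings.lmf_steps, seed=settings.seed)
        lmf.fit(cflc_tr, lmlc_tr)
        return (lmf.transform(cflc_tr, lmlc_tr),
                lmf.transform(cflc_te, lmlc_te))

    return build


def compare_fusion_methods(blocks: dict[str, FeatureTable],
                           methods: tuple[str, ...] = ("scca-lmf", "lmf",
                                                       "concat"),
                           svs: SvsConfig | None = None,
                           settings: FusionSettings | None = None
                           ) -> dict[str, "pd.Series"]:
    """Pooled 5-fold CV metrics for each fusion method on one cohort."""
    svs = svs or SvsConfig(fast=True)
    settings = settings or FusionSettings(seed=svs.seed)
    combined = concat_fuse([blocks["ffr"], blocks["arh"], blocks["lmlc"]])
    out = {}
    for method in methods:
        builder = make_feature_builder(method, settings)
        result = cross_validate_svs(combined, svs, feature_builder=builder)
        out[method] = pd.Series(result.pooled.as_dict())
    return out


def compare_svs_vs_bases(table: FeatureTable, svs: SvsConfig,
                         feature_builder=None) -> dict[str, float]:
    """CV accuracy of the full SVS ensemble and of each base learner alone
    on identical folds and identical (per-fold built) features.

    Single learners are trained on the same SMOTE-balanced training data;
    accuracies are pooled out-of-fold at each model's Youden threshold.
    """
    y = table.labels
    outer = StratifiedKFold(n_splits=svs.cv_folds, shuffle=True,
                            random_state=svs.seed)
    defs = _default_learners(svs.seed, svs.fast)
    scores: dict[str, np.ndarray] = {name: np.zeros(len(y))
                                     for name in ("svs",) + svs.base_learner_names}
    for tr, te in outer.split(table.values, y):
        train, test = table.subset_rows(tr), table.subset_rows(te)
        if feature_builder is not None:
            train, test = feature_builder(train, test)
        clf = SVSClassifier(svs).fit(train)
        scores["svs"][te] = clf.predict_scores(test)
        balanced = smote_oversample(train, svs.smote_k, svs.seed)
        for name in svs.base_learner_names:
            est, _ = defs[name]
            model = clone(est).fit(balanced.values, balanced.labels)
            scores[name][te] = model.predict_proba(
                test.select(train.feature_names).values)[:, 1]
    return {name: roc_curve(y, s).acc for name, s in scores.items()}


@dataclass
class BenchmarkResult:
    auc: pd.DataFrame                  # replicates x methods
    sign_test_p: float
    wins: int
    n_effective: int
    svs_accuracy: list[float]
    best_base_accuracy: list[float]

    @property
    def mean_auc(self) -> pd.Series:
        return self.auc.mean()

    @property
    def svs_margin(self) -> float:
        """mean(SVS accuracy) - mean(best single base learner accuracy)."""
        return float(np.mean(self.svs_accuracy)
                     - np.mean(self.best_base_accuracy))


def fusion_benchmark(n_replicates: int = 20, base_seed: int = 0,
                     spec: CohortSpec | None = None,
                     methods: tuple[str, ...] = ("scca-lmf", "concat"),
                     n_dominance: int = 10,
                     svs: SvsConfig | None = None,
                     settings: FusionSettings | None = None
                     ) -> BenchmarkResult:
    """Replicate benchmark: per-cohort pooled CV AUC per fusion method,
    the one-sided sign test of SCCA-LMF vs CONCAT, and (on the first
    ``n_dominance`` replicates) the SVS-vs-best-base accuracy comparison
    on the SCCA-LMF features."""
    template = spec or CohortSpec(duration=6.0)
    rows = []
    svs_acc, base_acc = [], []
    for rep in range(n_replicates):
        seed = (base_seed + 7919 * rep) % (2 ** 31)
        cohort = generate_cohort(replace(template, seed=seed))
        blocks = extract_representative_blocks(cohort)
        cfg = svs or SvsConfig(fast=True, seed=seed % 10_000)
        fs = settings or FusionSettings(seed=seed % 10_000)
        results = compare_fusion_methods(blocks, methods, cfg, fs)
        rows.append({m: results[m]["AUC"] for m in methods})
        if rep < n_dominance:
            combined = concat_fuse([blocks["ffr"], blocks["arh"],
                                    blocks["lmlc"]])
            builder = make_feature_builder("scca-lmf", fs)
            accs = compare_svs_vs_bases(combined, cfg, builder)
            svs_acc.append(accs["svs"])
            base_acc.append(max(accs[n] for n in cfg.base_learner_names))

    auc = pd.DataFrame(rows)
    diffs = auc["scca-lmf"] - auc["concat"]
    wins = int((diffs > 0).sum())
    n_eff = int((diffs != 0).sum())
    p = float(stats.binomtest(wins, n_eff, 0.5,
                              alternative="greater").pvalue) if n_eff else 1.0
    return BenchmarkResult(auc, p, wins, n_eff, svs_acc, base_acc)
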