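"""Confusion-matrix metrics, subject-wise splitting, streaming assessment
and the four-experiment comparison ladder.

Stress is the positive class throughout: sensitivity = TP/(TP+FN) is the
stress-detection rate, specificity = TN/(TN+FP) the non-stress rate, and
accuracy = (TP+TN)/total.  Splits are by *subject* — test subjects
contribute nothing to any training artifact (normalisation statistics,
class balancing, model weights).

The streaming harness consumes a recording in 1-second chunks through a
causal filter whose state is carried across chunks, so the streamed label
sequence is identical to batch prediction on the causally filtered signal;
wall time per chunk is reported, never asserted against any fixed value
(it is hardware-bound) — only the CNN-vs-feature-ML ordering is meaningful.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .eeg_io import Recording
from .labeling import NON_STRESS, STRESS
from .preprocess import DEFAULT_WINDOW_MS, FilterSpec, WindowTensor


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with stress as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    t = y_true == STRESS
    p = y_pred == STRESS
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from confusion counts."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive (stress) examples")
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative (non_stress) examples")
    sensitivity = c.tp / (c.tp + c.fn)
    specificity = c.tn / (c.tn + c.fp)
    accuracy = (c.tp + c.tn) / c.total
    return sensitivity, specificity, accuracy


@dataclass(frozen=True)
class SubjectSplit:
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.val), set(self.test)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("train/val/test subject sets must be disjoint")


@dataclass
class EvalReport:
    """Metrics plus provenance for one evaluation arm."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    latency_per_second_of_signal: float | None = None
    split: SubjectSplit | None = None

    def __post_init__(self) -> None:
        sens, spec, acc = metrics(self.counts)
        for got, want, name in (
            (self.sensitivity, sens, "sensitivity"),
            (self.specificity, spec, "specificity"),
            (self.accuracy, acc, "accuracy"),
        ):
            if abs(got - want) > 1e-9:
                raise ValueError(f"{name} inconsistent with confusion counts")

    def as_dict(self) -> dict:
        return {
            "tp": self.counts.tp, "fn": self.counts.fn,
            "tn": self.counts.tn, "fp": self.counts.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "latency_per_second_of_signal": self.latency_per_second_of_signal,
        }


def make_report(
    counts: ConfusionCounts,
    split: SubjectSplit | None = None,
    latency_per_second: float | None = None,
) -> EvalReport:
    sens, spec, acc = metrics(counts)
    return EvalReport(
        counts=counts, sensitivity=sens, specificity=spec, accuracy=acc,
        latency_per_second_of_signal=latency_per_second, split=split,
    )


def subject_split(
    subject_ids: list[str], n_train: int = 20, n_val: int = 3, n_test: int = 3, seed: int = 0
) -> SubjectSplit:
    """Seeded disjoint partition of a cohort into train/val/test subjects."""
    need = n_train + n_val + n_test
    if len(subject_ids) < need:
        raise ValueError(f"need at least {need} subjects, got {len(subject_ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subject_ids))
    ids = [subject_ids[i] for i in order]
    return SubjectSplit(
        train=tuple(ids[:n_train]),
        val=tuple(ids[n_train : n_train + n_val]),
        test=tuple(ids[n_train + n_val : need]),
    )


# ---------------------------------------------------------------------------
# streaming


class CnnStreamPipeline:
    """Causal-filter + window + CNN pipeline with filter state across chunks."""

    def __init__(self, model, filter_spec: FilterSpec = FilterSpec(), window_ms: float = DEFAULT_WINDOW_MS):
        if filter_spec.mode != "causal":
            raise ValueError("streaming requires a causal filter")
        self.model = model
        self.filter_spec = filter_spec
        self.window_ms = window_ms
        self._sos = None
        self._zi = None

    def reset(self, rec: Recording) -> None:
        self._sos = self.filter_spec.sos(rec.sampling_rate)
        n_chan = rec.data.shape[0]
        self._zi = np.zeros((self._sos.shape[0], n_chan, 2))

    def assess_chunk(self, chunk: np.ndarray, fs: float, subject_id: str) -> np.ndarray:
        from .cnn import predict_labels

        filtered, self._zi = sps.sosfilt(self._sos, chunk, axis=1, zi=self._zi)
        spw = round(self.window_ms * fs / 1000.0)
        n_win = filtered.shape[1] // spw
        data = filtered[:, : n_win * spw].reshape(filtered.shape[0], n_win, spw)
        tensor = WindowTensor(
            data=np.transpose(data, (0, 2, 1))[:, :, None, :],
            window_starts=np.arange(n_win) * (spw / fs),
            subject_id=subject_id,
            sampling_rate=fs,
        )
        return predict_labels(self.model, tensor)


class FeatureMlStreamPipeline:
    """Per-window band filtering + window features + a fitted classifier.

    Each 40 ms window is filtered in isolation (cold start), exactly as the
    batch window-mode feature extractor does, so streamed features equal
    batch features on the same samples.  The classifier must have been
    trained on the window-mode feature family (same band set and AAS-pair
    exclusion flag).
    """

    def __init__(
        self,
        classifier,
        band_set=None,
        exclude_aas_pair: bool = True,
        window_ms: float = DEFAULT_WINDOW_MS,
    ):
        from .features import BandSet

        self.classifier = classifier
        self.band_set = band_set or BandSet()
        self.exclude_aas_pair = exclude_aas_pair
        self.window_ms = window_ms
        self._sos: dict = {}
        self._montage = None

    def reset(self, rec: Recording) -> None:
        self._montage = rec.montage
        for b in self.band_set.names:
            lo, hi = self.band_set.edges(b)
            self._sos[b] = sps.butter(
                4, [lo, hi], btype="bandpass", fs=rec.sampling_rate, output="sos"
            )

    def assess_chunk(self, chunk: np.ndarray, fs: float, subject_id: str) -> np.ndarray:
        from .features import window_feature_matrix

        spw = round(self.window_ms * fs / 1000.0)
        n_win = chunk.shape[1] // spw
        windowed = chunk[:, : n_win * spw].reshape(chunk.shape[0], n_win, spw)
        band_windows = {b: sps.sosfilt(self._sos[b], windowed, axis=2) for b in self.band_set.names}
        matrix, names = window_feature_matrix(
            band_windows,
            self.band_set.names,
            list(self._montage.channel_names),
            list(self._montage.left_right_pairs),
            self.exclude_aas_pair,
        )
        import pandas as pd

        return self.classifier.predict(pd.DataFrame(matrix, columns=names))


def stream_assess(
    pipeline, rec: Recording, chunk_s: float = 1.0
) -> tuple[np.ndarray, list[float]]:
    """Consume a recording in ``chunk_s`` chunks; return (labels, per-chunk seconds).

    Single-pass: each sample enters the pipeline exactly once.  A 1 s chunk
    at 500 Hz yields 25 window predictions.
    """
    fs = rec.sampling_rate
    samples_per_chunk = round(chunk_s * fs)
    spw = round(pipeline.window_ms * fs / 1000.0)
    if samples_per_chunk < spw:
        raise ValueError(f"chunk of {chunk_s} s is shorter than one {pipeline.window_ms} ms window")
    pipeline.reset(rec)
    labels: list[np.ndarray] = []
    latencies: list[float] = []
    for start in range(0, rec.n_samples - samples_per_chunk + 1, samples_per_chunk):
        chunk = rec.data[:, start : start + samples_per_chunk]
        t0 = time.perf_counter()
        labels.append(pipeline.assess_chunk(chunk, fs, rec.subject_id))
        latencies.append(time.perf_counter() - t0)
    return np.concatenate(labels), latencies


# ---------------------------------------------------------------------------
# the four-experiment ladder


@dataclass(frozen=True)
class SuiteConfig:
    """Sizes, seeds and hyperparameters of the comparison ladder."""

    n_train: int = 20
    n_val: int = 3
    n_test: int = 3
    window_ms: float = DEFAULT_WINDOW_MS
    seed: int = 0
    max_train_rows: int | None = 4000  # ML-arm training subsample (kernel-SVM cost)
    cnn_feature_train_rows: int | None = 8000  # richer 1,320-dim features need more rows
    latency_seconds: int = 5  # chunks timed per pipeline
    cnn_spec: object | None = None  # CnnSpec; default built from seed
    train_cfg: object | None = None  # TrainConfig; default built from seed
    aas_cfg: object | None = None  # AasConfig; default AasConfig()
    filter_spec: FilterSpec = FilterSpec()  # causal 4-30 Hz


@dataclass
class SuiteResult:
    """One EvalReport per arm plus the feature-cross-validation reports."""

    split: SubjectSplit
    exp1_batch_ml: dict
    exp2_window_session_ml: dict
    exp3_window_aas_ml: dict
    exp4_cnn: EvalReport
    cnn_feature_ml: dict
    latency_cnn: float
    latency_feature_ml: float
    comparison: object | None = None  # pandas DataFrame

    def arm_accuracy(self, arm: str) -> float:
        """Best test accuracy of an arm ('exp1'..'exp4')."""
        if arm == "exp4":
            return self.exp4_cnn.accuracy
        reports = {"exp1": self.exp1_batch_ml, "exp2": self.exp2_window_session_ml,
                   "exp3": self.exp3_window_aas_ml, "cnn_features": self.cnn_feature_ml}[arm]
        return max(r.accuracy for r in reports.values())


def experiment_suite(cohort: list[Recording], config: SuiteConfig = SuiteConfig()) -> SuiteResult:
    """Run the full comparison ladder on one cohort.

    Arms: (1) whole-session features + session labels + ML; (2) 40 ms window
    features + session labels + ML; (3) 40 ms window features + AAS labels
    (prefrontal alpha asymmetry excluded from the features) + ML; (4) raw
    40 ms windows + AAS labels + CNN; plus ML classifiers retrained on the
    CNN's flattened features, and a paired streaming-latency measurement.
    """
    import pandas as pd

    from . import cnn as cnn_mod
    from .features import FeatureConfig, concat_tables, extract_features, fit_baselines
    from .labeling import AasConfig, balance_classes, label_windows
    from .preprocess import bandpass, concat_tensors, segment_windows

    seed = config.seed
    aas_cfg = config.aas_cfg or AasConfig()
    cnn_spec = config.cnn_spec or cnn_mod.CnnSpec(seed=seed)
    train_cfg = config.train_cfg or cnn_mod.TrainConfig(seed=seed)

    ids = [rec.subject_id for rec in cohort]
    split = subject_split(ids, config.n_train, config.n_val, config.n_test, seed=seed)
    by_id = {rec.subject_id: rec for rec in cohort}

    # --- shared window artifacts per subject (single 4-30 Hz causal pass) ---
    tensors: dict[str, WindowTensor] = {}
    aas_labels: dict[str, object] = {}
    for sid, rec in by_id.items():
        filtered = bandpass(rec, config.filter_spec)
        tensors[sid] = segment_windows(filtered, config.window_ms)
        aas_labels[sid] = label_windows(rec, tensors[sid], aas_cfg)

    # --- experiments 1-3: feature tables ---
    exp1_tables, exp2_tables, exp3_tables = [], [], []
    for sid, rec in by_id.items():
        exp1_tables.append(extract_features(rec, "batch_session"))
        exp2_tables.append(extract_features(rec, "window_40ms"))
        exp3_tables.append(
            extract_features(
                rec, "window_40ms", labels=aas_labels[sid],
                config=FeatureConfig(exclude_aas_pair=True),
            )
        )
    exp1 = fit_baselines(concat_tables(exp1_tables), split, seed=seed)
    exp2 = fit_baselines(
        concat_tables(exp2_tables), split, seed=seed, max_train_rows=config.max_train_rows
    )
    exp3, exp3_models = fit_baselines(
        concat_tables(exp3_tables), split, seed=seed,
        max_train_rows=config.max_train_rows, return_models=True,
    )

    # --- experiment 4: CNN on balanced AAS-labeled training windows ---
    train_sets = [aas_labels[sid] for sid in split.train]
    kept = balance_classes(train_sets, seed=seed)
    train_parts, train_y, train_sub_ids = [], [], []
    for (i, idx) in kept:
        sid = split.train[i]
        train_parts.append(tensors[sid].subset(idx))
        train_y.append(aas_labels[sid].label[idx])
        train_sub_ids.append(np.full(len(idx), sid, dtype=object))
    train_tensor = concat_tensors(train_parts)
    train_labels = np.concatenate(train_y)
    train_subjects = np.concatenate(train_sub_ids)

    val_tensor = concat_tensors([tensors[s] for s in split.val])
    val_labels = np.concatenate([aas_labels[s].label for s in split.val])
    test_tensor = concat_tensors([tensors[s] for s in split.test])
    test_labels = np.concatenate([aas_labels[s].label for s in split.test])

    model = cnn_mod.train(cnn_spec, train_cfg, train_tensor, train_labels, val_tensor, val_labels)
    pred = cnn_mod.predict_labels(model, test_tensor)
    exp4 = make_report(confusion_from_labels(test_labels, pred), split=split)

    # --- cross-validation of CNN features ---
    rng = np.random.default_rng(seed)
    n_tr = train_tensor.n_windows
    take = min(config.cnn_feature_train_rows or n_tr, n_tr)
    sub = np.sort(rng.choice(n_tr, size=take, replace=False))
    feat_train = cnn_mod.extract_cnn_features(
        model, train_tensor.subset(sub), labels=train_labels[sub], subjects=train_subjects[sub]
    )
    feat_test = cnn_mod.extract_cnn_features(
        model, test_tensor, labels=test_labels,
        subjects=np.concatenate([np.full(tensors[s].n_windows, s, dtype=object) for s in split.test]),
    )
    from .features import concat_tables as _ct

    cnn_feat = fit_baselines(_ct([feat_train, feat_test]), split, seed=seed)

    # --- paired streaming latency on one held-out recording ---
    latency_rec = by_id[split.test[0]]
    n_lat = round(config.latency_seconds * latency_rec.sampling_rate)
    lat_rec = latency_rec.copy_with(data=latency_rec.data[:, :n_lat], annotations=[])
    cnn_pipe = CnnStreamPipeline(model, config.filter_spec, config.window_ms)
    _, lat_cnn = stream_assess(cnn_pipe, lat_rec)
    # paired against the kernel-SVM feature pipeline, the reference
    # conventional-ML technique for this task
    ml_pipe = FeatureMlStreamPipeline(exp3_models["svm_rbf"], exclude_aas_pair=True,
                                      window_ms=config.window_ms)
    _, lat_ml = stream_assess(ml_pipe, lat_rec)

    rows = []
    for arm, reports in (
        ("exp1_batch_session_ml", exp1),
        ("exp2_window_session_ml", exp2),
        ("exp3_window_aas_ml", exp3),
        ("cnn_feature_ml", cnn_feat),
    ):
        for algo, rep in reports.items():
            rows.append({"arm": arm, "classifier": algo, **rep.as_dict()})
    rows.append({"arm": "exp4_cnn", "classifier": "cnn", **exp4.as_dict()})
    comparison = pd.DataFrame(rows)

    return SuiteResult(
        split=split,
        exp1_batch_ml=exp1,
        exp2_window_session_ml=exp2,
        exp3_window_aas_ml=exp3,
        exp4_cnn=exp4,
        cnn_feature_ml=cnn_feat,
        latency_cnn=float(np.median(lat_cnn)),
        latency_feature_ml=float(np.median(lat_ml)),
        comparison=comparison,
    )
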