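"""Conventional feature-based ML path: spectral and connectivity features.

This is the comparison arm of the package: per-segment band power, relative
power, power ratios, magnitude-squared coherence and left/right log-power
asymmetries, fed to off-the-shelf decision-tree / logistic-regression /
RBF-SVM classifiers.

Two estimator regimes are used depending on segment length.  Long segments
(>= 125 ms) use Welch periodograms and Welch coherence.  40 ms windows are
too short for spectral estimators (a 20-sample FFT has 25 Hz resolution), so
window mode band-filters each 40 ms window *in isolation* (causal, cold
start) — the estimator a per-window real-time pipeline applies to the slice
it just received — and uses filtered variance for power and squared Pearson
correlation of the filtered pair as the coherence surrogate.  Surrogate coherence
columns are named ``cohw[...]`` (vs ``coh[...]``) so tables from the two
regimes are never silently mixed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .eeg_io import Recording
from .labeling import NON_STRESS, STRESS, WindowLabelSet
from .preprocess import FilterSpec, bandpass, segment_windows

#: Shortest segment (seconds) for which Welch estimators are used.
WELCH_MIN_S = 0.125

_EPS = 1e-12


@dataclass(frozen=True)
class BandSet:
    """Named, frequency-ordered, non-overlapping EEG bands."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 12.0),
        ("beta", 13.0, 30.0),
    )

    def __post_init__(self) -> None:
        prev_hi = 0.0
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name} has lo >= hi")
            if lo < prev_hi:
                raise ValueError("bands must be non-overlapping and frequency-ordered")
            prev_hi = hi

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def edges(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return lo, hi
        raise KeyError(name)


#: Band set including delta, for batch-mode features on the raw signal.
BANDS_WITH_DELTA = BandSet(
    bands=(
        ("delta", 0.5, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 12.0),
        ("beta", 13.0, 30.0),
    )
)


@dataclass
class FeatureTable:
    """Per-segment named feature vectors with labels and provenance."""

    frame: pd.DataFrame
    label: np.ndarray
    subject: np.ndarray
    segment: np.ndarray

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=object)
        self.subject = np.asarray(self.subject, dtype=object)
        self.segment = np.asarray(self.segment)
        n = len(self.frame)
        if not (len(self.label) == len(self.subject) == len(self.segment) == n):
            raise ValueError("label/subject/segment lengths must match the frame")
        if self.frame.isna().to_numpy().any():
            raise ValueError("feature table contains NaN")

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    def rows_for_subjects(self, subjects: list[str]) -> np.ndarray:
        wanted = set(subjects)
        return np.flatnonzero(np.array([s in wanted for s in self.subject]))


def concat_tables(tables: list["FeatureTable"]) -> FeatureTable:
    if not tables:
        raise ValueError("no tables to concatenate")
    cols = tables[0].feature_names
    for t in tables[1:]:
        if t.feature_names != cols:
            raise ValueError("feature names differ across tables; refusing to mix")
    return FeatureTable(
        frame=pd.concat([t.frame for t in tables], ignore_index=True),
        label=np.concatenate([t.label for t in tables]),
        subject=np.concatenate([t.subject for t in tables]),
        segment=np.concatenate([t.segment for t in tables]),
    )


# ---------------------------------------------------------------------------
# per-segment estimators


def band_power(
    segment: np.ndarray, band: tuple[float, float], sampling_rate: float
) -> np.ndarray:
    """Per-channel power (uV^2) of ``segment`` ([channels x samples]) in ``band``.

    Welch periodogram integral for segments >= 125 ms; filtered variance for
    shorter ones (where spectral bins cannot resolve the band).
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=np.float64))
    lo, hi = band
    if hi >= sampling_rate / 2:
        raise ValueError(f"band {band} reaches Nyquist ({sampling_rate / 2} Hz)")
    n = segment.shape[1]
    if n < 2:
        raise ValueError("segment must have at least 2 samples")
    if n / sampling_rate >= WELCH_MIN_S:
        nperseg = min(n, int(sampling_rate))
        freqs, psd = sps.welch(segment, fs=sampling_rate, nperseg=nperseg, axis=1)
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            mask = (freqs >= lo) & (freqs <= hi + freqs[1])
        return np.trapezoid(psd[:, mask], freqs[mask], axis=1)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")
    filtered = sps.sosfilt(sos, segment, axis=1)
    return np.mean(filtered**2, axis=1)


def relative_power(powers: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """power[b] / sum over bands, per channel; errors on an all-zero channel."""
    total = np.sum(list(powers.values()), axis=0)
    if np.any(total <= 0):
        raise ValueError("channel with zero total power; relative power undefined")
    return {b: p / total for b, p in powers.items()}


def power_ratios(powers: dict[str, np.ndarray], order: list[str] | None = None) -> dict[str, np.ndarray]:
    """Pairwise quotients power[b_i]/power[b_j] for i < j in band order."""
    names = order if order is not None else list(powers)
    out = {}
    for i, bi in enumerate(names):
        for bj in names[i + 1 :]:
            out[f"{bi}/{bj}"] = powers[bi] / (powers[bj] + _EPS)
    return out


def coherence(
    segment: np.ndarray,
    channel_pair: tuple[int, int],
    band: tuple[float, float],
    sampling_rate: float,
    mode: str = "auto",
) -> float:
    """Band-averaged coupling of two channels, in [0, 1].

    ``welch``: magnitude-squared coherence averaged over in-band frequencies
    (requires >= 2 averaging segments).  ``surrogate``: squared Pearson
    correlation of the band-filtered pair, the only meaningful estimator for
    20-sample windows.
    """
    segment = np.asarray(segment, dtype=np.float64)
    i, j = channel_pair
    x, y = segment[i], segment[j]
    n = x.size
    lo, hi = band
    if mode == "auto":
        mode = "welch" if n / sampling_rate >= 2 * WELCH_MIN_S else "surrogate"
    if mode == "welch":
        nperseg = min(n // 2, int(sampling_rate))
        if n / sampling_rate < 2 * WELCH_MIN_S or nperseg < 8:
            raise ValueError("segment too short for Welch coherence; use mode='surrogate'")
        freqs, coh = sps.coherence(x, y, fs=sampling_rate, nperseg=nperseg)
        mask = (freqs >= lo) & (freqs <= hi)
        if not mask.any():
            raise ValueError("no coherence bins inside the band")
        return float(np.clip(np.mean(coh[mask]), 0.0, 1.0))
    if mode == "surrogate":
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")
        fx = sps.sosfilt(sos, x)
        fy = sps.sosfilt(sos, y)
        return float(np.clip(_corr_sq(fx, fy), 0.0, 1.0))
    raise ValueError(f"unknown coherence mode {mode!r}")


def _coherence_matrix_welch(
    segment: np.ndarray, sampling_rate: float, nperseg: int
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs magnitude-squared coherence via one Hann-windowed STFT.

    Matches :func:`scipy.signal.coherence` defaults (hann window, 50%%
    overlap, constant detrend, mean averaging) but computes the full
    [freqs x channels x channels] matrix in one pass.
    """
    segment = np.asarray(segment, dtype=np.float64)
    n_chan, n = segment.shape
    step = nperseg - nperseg // 2
    n_frames = 1 + (n - nperseg) // step
    if n_frames < 2:
        raise ValueError("segment too short for Welch coherence")
    win = sps.get_window("hann", nperseg)
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_frames)[:, None]
    frames = segment[:, idx]  # (chan, frames, nperseg)
    frames = frames - frames.mean(axis=2, keepdims=True)
    spec = np.fft.rfft(frames * win, axis=2)  # (chan, frames, freqs)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / sampling_rate)
    cross = np.einsum("ctf,dtf->fcd", spec, np.conj(spec)) / n_frames
    auto = np.real(np.einsum("fcc->fc", cross))
    denom = auto[:, :, None] * auto[:, None, :]
    coh = np.abs(cross) ** 2 / np.where(denom <= 0, 1.0, denom)
    return freqs, np.clip(coh, 0.0, 1.0)


def _corr_sq(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        return 0.0
    return float(((x * y).sum() / denom) ** 2)


def asymmetry_features(
    powers: dict[str, np.ndarray],
    pairs: list[tuple[str, str]],
    channel_names: list[str],
    exclude_aas_pair: bool = False,
    aas_band: str = "alpha",
    aas_pair: tuple[str, str] = ("Fp1", "Fp2"),
) -> dict[str, float | np.ndarray]:
    """ln(right power) - ln(left power) per band per homologous pair.

    With ``exclude_aas_pair`` the prefrontal alpha asymmetry is omitted: in
    the AAS-labeled experiments it is the label source and would leak the
    target into the features.
    """
    idx = {c: i for i, c in enumerate(channel_names)}
    out = {}
    for left, right in pairs:
        if left not in idx or right not in idx:
            raise KeyError(f"pair ({left}, {right}) not in channel list")
        for band, p in powers.items():
            if exclude_aas_pair and band == aas_band and (left, right) == aas_pair:
                continue
            out[f"asym[{band},{left}-{right}]"] = np.log(p[..., idx[right]] + _EPS) - np.log(
                p[..., idx[left]] + _EPS
            )
    return out


# ---------------------------------------------------------------------------
# table extraction


@dataclass(frozen=True)
class FeatureConfig:
    band_set: BandSet | None = None  # default: +delta in batch mode, without in window mode
    exclude_aas_pair: bool = False
    window_ms: float = 40.0
    coherence_pairs: str = "all"  # all off-diagonal channel pairs


def _session_segments(rec: Recording) -> list[tuple[str, str, np.ndarray]]:
    """(session_name, label, [channels x samples]) per annotated condition."""
    if not rec.annotations:
        raise ValueError(f"recording {rec.subject_id} has no session annotations")
    segs = []
    for name, start, end in rec.annotations:
        i0 = round(start * rec.sampling_rate)
        i1 = round(end * rec.sampling_rate)
        label = STRESS if name == "stress_task" else NON_STRESS
        segs.append((name, label, rec.data[:, i0:i1]))
    return segs


def extract_features(
    rec: Recording,
    mode: str,
    labels: WindowLabelSet | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureTable:
    """Build the full feature family for one recording.

    ``batch_session`` mode emits one row per annotated session, labelled by
    the session condition.  ``window_40ms`` emits one row per 40 ms window,
    labelled by ``labels`` (an AAS label set) when given, else by the session
    containing the window.
    """
    if mode == "batch_session":
        return _extract_batch(rec, config)
    if mode == "window_40ms":
        return _extract_windows(rec, labels, config)
    raise ValueError(f"unknown mode {mode!r}")


def _channel_pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def _extract_batch(rec: Recording, config: FeatureConfig) -> FeatureTable:
    band_set = config.band_set or BANDS_WITH_DELTA
    chans = list(rec.montage.channel_names)
    pairs = _channel_pairs(len(chans))
    rows, labels, segments = [], [], []
    for name, label, seg in _session_segments(rec):
        powers = {b: band_power(seg, band_set.edges(b), rec.sampling_rate) for b in band_set.names}
        rel = relative_power(powers)
        ratios = power_ratios(powers, band_set.names)
        feats: dict[str, float] = {}
        for b in band_set.names:
            for ci, c in enumerate(chans):
                feats[f"power[{b},{c}]"] = powers[b][ci]
                feats[f"relpower[{b},{c}]"] = rel[b][ci]
        for rname, vals in ratios.items():
            for ci, c in enumerate(chans):
                feats[f"ratio[{rname},{c}]"] = vals[ci]
        nperseg = min(seg.shape[1] // 2, int(rec.sampling_rate))
        freqs, coh_mat = _coherence_matrix_welch(seg, rec.sampling_rate, nperseg)
        for b in band_set.names:
            lo, hi = band_set.edges(b)
            mask = (freqs >= lo) & (freqs <= hi)
            band_coh = coh_mat[mask].mean(axis=0)
            for i, j in pairs:
                feats[f"coh[{b},{chans[i]}-{chans[j]}]"] = float(band_coh[i, j])
        asym = asymmetry_features(
            powers, list(rec.montage.left_right_pairs), chans,
            exclude_aas_pair=config.exclude_aas_pair,
        )
        feats.update({k: float(v) for k, v in asym.items()})
        rows.append(feats)
        labels.append(label)
        segments.append(name)
    frame = pd.DataFrame(rows)
    return FeatureTable(
        frame=frame,
        label=np.array(labels, dtype=object),
        subject=np.array([rec.subject_id] * len(rows), dtype=object),
        segment=np.array(segments, dtype=object),
    )


def _extract_windows(
    rec: Recording, labels: WindowLabelSet | None, config: FeatureConfig
) -> FeatureTable:
    band_set = config.band_set or BandSet()
    chans = list(rec.montage.channel_names)
    n_chan = len(chans)
    fs = rec.sampling_rate
    spw = round(config.window_ms * fs / 1000.0)
    n_win = rec.n_samples // spw
    n_keep = n_win * spw

    if labels is not None and labels.n_windows != n_win:
        raise ValueError("label set does not match the window count of this recording")

    # Each 40 ms window is filtered *in isolation* (causal, cold start):
    # the per-window estimator a real-time deployment applies to the slice
    # it just received, and byte-identical to FeatureMlStreamPipeline fed
    # the same samples.  The cold-start transient makes these features lossy
    # at this window length — that loss is a property of the conventional
    # path, not an implementation accident; only the labeling stage uses the
    # offline zero-phase filter.
    windowed = rec.data[:, :n_keep].reshape(n_chan, n_win, spw)
    band_windows: dict[str, np.ndarray] = {}
    for b in band_set.names:
        lo, hi = band_set.edges(b)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        band_windows[b] = sps.sosfilt(sos, windowed, axis=2)

    matrix, names = window_feature_matrix(
        band_windows, band_set.names, chans,
        list(rec.montage.left_right_pairs), config.exclude_aas_pair,
    )
    frame = pd.DataFrame(matrix.astype(np.float32), columns=names)

    if labels is not None:
        row_labels = labels.label.copy()
    else:
        starts = np.arange(n_win) * (spw / fs)
        row_labels = np.array([_session_label_at(rec, s, spw / fs) for s in starts], dtype=object)
    return FeatureTable(
        frame=frame,
        label=row_labels,
        subject=np.array([rec.subject_id] * n_win, dtype=object),
        segment=np.arange(n_win),
    )


def window_feature_matrix(
    band_windows: dict[str, np.ndarray],
    band_names: list[str],
    chans: list[str],
    lr_pairs: list[tuple[str, str]],
    exclude_aas_pair: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Window-mode feature family from per-band windowed traces.

    ``band_windows[b]`` is ``[channels x n_windows x samples_per_window]`` of
    the band-filtered signal.  Shared by batch extraction and the streaming
    path so both emit byte-identical feature layouts.
    """
    n_chan = len(chans)
    powers = {b: np.mean(w**2, axis=2).T for b, w in band_windows.items()}  # (n_win, n_chan)
    total = np.sum(list(powers.values()), axis=0)
    total = np.where(total <= 0, _EPS, total)
    rel = {b: p / total for b, p in powers.items()}
    ratios = power_ratios(powers, band_names)

    blocks: list[np.ndarray] = []
    names: list[str] = []
    for b in band_names:
        blocks.append(powers[b])
        names += [f"power[{b},{c}]" for c in chans]
    for b in band_names:
        blocks.append(rel[b])
        names += [f"relpower[{b},{c}]" for c in chans]
    for rname, vals in ratios.items():
        blocks.append(vals)
        names += [f"ratio[{rname},{c}]" for c in chans]

    pairs = _channel_pairs(n_chan)
    iu = np.triu_indices(n_chan, k=1)
    for b in band_names:
        w = band_windows[b]  # (chan, win, spw)
        z = w - w.mean(axis=2, keepdims=True)
        norm = np.sqrt(np.sum(z**2, axis=2))
        norm = np.where(norm == 0, 1.0, norm)
        z = z / norm[:, :, None]
        corr = np.einsum("cws,dws->wcd", z, z)  # (win, chan, chan)
        blocks.append(np.clip(corr[:, iu[0], iu[1]] ** 2, 0.0, 1.0))
        names += [f"cohw[{b},{chans[i]}-{chans[j]}]" for i, j in pairs]

    asym = asymmetry_features(powers, lr_pairs, chans, exclude_aas_pair=exclude_aas_pair)
    for k, v in asym.items():
        blocks.append(np.asarray(v)[:, None])
        names.append(k)
    return np.concatenate(blocks, axis=1), names


def _session_label_at(rec: Recording, start_s: float, window_s: float) -> str:
    mid = start_s + window_s / 2
    for name, s0, s1 in rec.annotations:
        if s0 <= mid < s1:
            return STRESS if name == "stress_task" else NON_STRESS
    return NON_STRESS


# ---------------------------------------------------------------------------
# baseline classifiers


BASELINE_ALGOS = ("decision_tree", "logistic_regression", "svm_rbf")


def _make_classifier(algo: str, seed: int):
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    if algo == "decision_tree":
        return DecisionTreeClassifier(max_depth=20, random_state=seed)
    if algo == "logistic_regression":
        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed))
    if algo == "svm_rbf":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", gamma="scale", random_state=seed))
    raise ValueError(f"unknown algorithm {algo!r}; choose from {BASELINE_ALGOS}")


def fit_baselines(
    table: FeatureTable,
    split,
    algos: tuple[str, ...] = BASELINE_ALGOS,
    seed: int = 0,
    max_train_rows: int | None = None,
    return_models: bool = False,
):
    """Train and evaluate the conventional classifiers subject-wise.

    ``split`` carries train/test subject id lists (see
    :func:`stresswin.evaluation.subject_split`).  ``max_train_rows``
    subsamples the training rows (seeded) to bound kernel-SVM cost; the test
    rows are never subsampled.  Returns ``{algo: EvalReport}``.
    """
    from .evaluation import confusion_from_labels, make_report

    train_idx = table.rows_for_subjects(split.train)
    test_idx = table.rows_for_subjects(split.test)
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("split selects no training or no test rows")
    y_train = table.label[train_idx]
    if len(set(y_train)) < 2:
        raise ValueError("training rows contain a single class; cannot fit classifiers")

    rng = np.random.default_rng(seed)
    if max_train_rows is not None and len(train_idx) > max_train_rows:
        train_idx = rng.choice(train_idx, size=max_train_rows, replace=False)
        y_train = table.label[train_idx]
        if len(set(y_train)) < 2:
            raise ValueError("training subsample lost a class; increase max_train_rows")

    X = table.frame.to_numpy(dtype=np.float64)
    X_train, X_test = X[train_idx], X[test_idx]
    y_test = table.label[test_idx]

    reports = {}
    models = {}
    for algo in algos:
        clf = _make_classifier(algo, seed)
        clf.fit(X_train, y_train)
        t0 = time.perf_counter()
        pred = clf.predict(X_test)
        predict_time = time.perf_counter() - t0
        counts = confusion_from_labels(y_test, pred)
        # prediction-only wall time scaled to one second of signal (25 windows
        # at 40 ms); the full streaming latency comes from stream_assess
        per_second = predict_time / max(len(test_idx), 1) * 25.0
        reports[algo] = make_report(counts, split=split, latency_per_second=per_second)
        models[algo] = clf
    if return_models:
        return reports, models
    return reports
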