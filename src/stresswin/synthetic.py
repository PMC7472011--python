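"""Synthetic 19-channel EEG with a planted frontal alpha asymmetry.

The generator emulates the geometry of a two-condition stress study: each
subject contributes one continuous recording holding a *relax* session
followed by a *stress_task* session (5 min each at 500 Hz by default).  Every
channel is a sum of band-limited oscillations (delta/theta/alpha/beta, each a
mixture of random-frequency random-phase sinusoids) on top of 1/f^beta
background noise.

The stress manipulation is planted only where the labeling stage looks for
it: the prefrontal pair Fp1/Fp2 shares one alpha waveform per subject whose
amplitudes are scaled to a controllable right/left ratio ``r`` per condition.
With the log-power asymmetry convention the per-window score has expectation
``2 ln r``, so ``r > 1`` plants positive (relaxed) and ``r < 1`` negative
(stressed) asymmetry.  All other channels are left symmetric.

Mental-stress patterns are instantaneous: a session recorded under one
condition still contains brief episodes of the opposite state.  The
generator emulates this by flipping the planted asymmetry on a small
fraction of short sub-epochs (``transient_fraction`` of ``transient_s``
blocks) inside each session, so session-level labels are an imperfect
description of individual 40 ms windows while per-window asymmetry labels
remain exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eeg_io import Montage, Recording

#: Conventional EEG band edges in Hz used for generation.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}

#: Per-band component amplitude in microvolts.  The convention is that a band
#: with amplitude A carries total power A^2/2, like a single sinusoid of
#: amplitude A.  Values are in the range typical of scalp EEG (alpha tens of
#: microvolts, beta a few).
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 20.0,
    "theta": 10.0,
    "alpha": 20.0,
    "beta": 5.0,
}


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic cohort.

    ``asym_relax`` / ``asym_stress`` are the Fp2/Fp1 alpha-amplitude ratios
    planted in the two conditions; defaults 2.0 and 0.5 plant asymmetries of
    equal magnitude and opposite sign.
    """

    n_subjects: int = 26
    session_length: float = 300.0  # seconds per condition; two conditions
    sampling_rate: float = 500.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BANDS))
    asym_relax: float = 2.0
    asym_stress: float = 0.5
    noise_exponent: float = 1.0
    noise_amplitude: float = 10.0  # RMS microvolts of the 1/f background
    transient_fraction: float = 0.1  # share of sub-epochs with flipped asymmetry
    transient_s: float = 0.2  # sub-epoch duration in seconds
    sinusoids_per_band: int = 8
    prefrontal_alpha_components: int = 1  # shared Fp1/Fp2 alpha is narrowband
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(a < 0 for a in self.band_amplitudes.values()) or self.noise_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.asym_relax <= 0 or self.asym_stress <= 0:
            raise ValueError("asymmetry ratios must be positive")
        if not 0.0 <= self.transient_fraction < 0.5:
            raise ValueError("transient_fraction must be in [0, 0.5)")
        n = self.session_length * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("session_length x sampling_rate must be an integral sample count")

    @property
    def samples_per_session(self) -> int:
        return round(self.session_length * self.sampling_rate)


def _band_frequencies(rng: np.random.Generator, lo: float, hi: float, k: int) -> np.ndarray:
    # keep a small margin from the band edges so filter roll-off at the edges
    # does not blur the planted band structure
    margin = 0.05 * (hi - lo)
    return rng.uniform(lo + margin, hi - margin, size=k)


def _sinusoid_mixture(
    rng: np.random.Generator, t: np.ndarray, lo: float, hi: float, amplitude: float, k: int
) -> np.ndarray:
    """Sum of k random in-band sinusoids with total power amplitude^2/2."""
    freqs = _band_frequencies(rng, lo, hi, k)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
    comp = amplitude / np.sqrt(k)
    out = np.zeros_like(t)
    for f, ph in zip(freqs, phases):
        out += comp * np.sin(2.0 * np.pi * f * t + ph)
    return out


def _pink_noise(rng: np.random.Generator, n: int, beta: float, rms: float, fs: float) -> np.ndarray:
    """1/f^beta noise via spectral shaping of white noise, scaled to given RMS."""
    if rms == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-beta / 2.0)
    shape[0] = 0.0  # no DC offset
    shaped = np.fft.irfft(spec * shape, n=n)
    current = np.sqrt(np.mean(shaped**2))
    return shaped * (rms / current)


def _epoch_ratio_track(
    rng: np.random.Generator,
    n: int,
    fs: float,
    ratio_main: float,
    ratio_other: float,
    transient_fraction: float,
    transient_s: float,
) -> np.ndarray:
    """Per-sample asymmetry ratio for one session: mostly ``ratio_main`` with
    ``transient_fraction`` of ``transient_s`` sub-epochs flipped to ``ratio_other``."""
    track = np.full(n, ratio_main)
    if transient_fraction <= 0:
        return track
    block = max(1, round(transient_s * fs))
    n_blocks = n // block
    flips = rng.random(n_blocks) < transient_fraction
    for b in np.flatnonzero(flips):
        track[b * block : (b + 1) * block] = ratio_other
    return track


def generate_recording(spec: SynthSpec, subject_index: int) -> Recording:
    """Generate one subject's two-session recording.

    Deterministic given ``(spec.seed, subject_index)``: each subject draws
    from an independent child stream of the master seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_index]))
    montage = Montage()
    fs = spec.sampling_rate
    n_sess = spec.samples_per_session
    n_total = 2 * n_sess
    t = np.arange(n_total) / fs

    data = np.zeros((len(montage.channel_names), n_total))

    i_fp1 = montage.index("Fp1")
    i_fp2 = montage.index("Fp2")

    # Shared prefrontal alpha waveform, scaled per condition epoch.  The
    # shared generator is narrowband (default: one alpha-frequency
    # oscillation per subject), matching the peaked spectrum of the resting
    # alpha rhythm; a constant envelope keeps the planted power ratio
    # meaningful at the 40 ms window scale.
    alpha_lo, alpha_hi = spec.bands["alpha"]
    alpha_amp = spec.band_amplitudes.get("alpha", 0.0)
    shared_alpha = _sinusoid_mixture(
        rng, t, alpha_lo, alpha_hi, alpha_amp, spec.prefrontal_alpha_components
    )
    # relax session first, then the stress task; inside each session a small
    # fraction of short sub-epochs carries the opposite condition's asymmetry
    ratio = np.empty(n_total)
    ratio[:n_sess] = _epoch_ratio_track(
        rng, n_sess, fs, spec.asym_relax, spec.asym_stress, spec.transient_fraction, spec.transient_s
    )
    ratio[n_sess:] = _epoch_ratio_track(
        rng, n_sess, fs, spec.asym_stress, spec.asym_relax, spec.transient_fraction, spec.transient_s
    )
    data[i_fp1] += shared_alpha / np.sqrt(ratio)
    data[i_fp2] += shared_alpha * np.sqrt(ratio)

    for ci in range(len(montage.channel_names)):
        for band, (lo, hi) in spec.bands.items():
            amp = spec.band_amplitudes.get(band, 0.0)
            if band == "alpha" and ci in (i_fp1, i_fp2):
                continue  # alpha planted above for the prefrontal pair
            if amp > 0:
                data[ci] += _sinusoid_mixture(rng, t, lo, hi, amp, spec.sinusoids_per_band)
        data[ci] += _pink_noise(rng, n_total, spec.noise_exponent, spec.noise_amplitude, fs)

    annotations = [
        ("relax", 0.0, spec.session_length),
        ("stress_task", spec.session_length, 2.0 * spec.session_length),
    ]
    return Recording(
        subject_id=f"synth{subject_index:03d}",
        data=data,
        sampling_rate=fs,
        montage=montage,
        annotations=annotations,
    )


def generate_cohort(spec: SynthSpec) -> list[Recording]:
    """Generate ``spec.n_subjects`` recordings with distinct per-subject streams."""
    return [generate_recording(spec, i) for i in range(spec.n_subjects)]
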