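"""Acoustic and electrical stimulus construction.

Builds the stimulus set used throughout the pipeline: 25 ms tone pips on a
log-frequency x level grid (1-32 kHz, 0-75 dB SPL), six-burst noise trains at
7.5-15 Hz, synthetic consonant-vowel speech proxies, the 30 Hz vagus-nerve
stimulation (VNS) pulse train, and randomized VNS-sound pairing session
schedules.  Everything is bit-reproducible given a seed.

Sound level convention: dB SPL is modeled as ``20*log10(rms/ref)`` with the
package reference fixed so that a full-scale sine (amplitude 1.0) measures
94 dB SPL.  Absolute SPL is therefore a bookkeeping convention -- there is no
microphone in software -- but all relative level arithmetic is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ToneStimulus",
    "NoiseBurstTrain",
    "SpeechStimulus",
    "VNSTrain",
    "PairingSchedule",
    "SPEECH_LABELS",
    "STOP_LABELS",
    "FULL_SCALE_SINE_DB",
    "calibrate_speech_level",
    "rms_level_db",
    "loudest_window_level",
    "make_tone_grid",
    "make_noise_train",
    "make_vns_train",
    "make_pairing_schedule",
    "synth_speech_proxy",
]

#: dB SPL assigned to a full-scale (amplitude 1.0) sine wave.
FULL_SCALE_SINE_DB = 94.0
_REF_RMS = 1.0 / math.sqrt(2.0)  # RMS of a full-scale sine

SPEECH_LABELS = ("dad", "bad", "gad", "tad", "sad", "rad", "lad")
#: tokens whose initial consonant is a stop (abrupt broadband onset)
STOP_LABELS = ("bad", "tad", "gad", "dad")

NOISE_TRAIN_RATES = (7.5, 10.0, 12.5, 15.0)


@dataclass(frozen=True)
class ToneStimulus:
    """A 25 ms tone pip at one (frequency, level) grid point."""

    frequency: float  # Hz
    level: float      # dB SPL
    duration: float = 25.0  # ms

    def __post_init__(self):
        if not (1000.0 <= self.frequency <= 32000.0):
            raise ValueError(f"tone frequency {self.frequency} Hz outside [1, 32] kHz")
        if not (0.0 <= self.level <= 75.0):
            raise ValueError(f"tone level {self.level} dB outside [0, 75] dB SPL")
        if self.duration <= 0:
            raise ValueError("tone duration must be positive")


@dataclass(frozen=True)
class NoiseBurstTrain:
    """Six 25 ms noise bursts at a fixed repetition rate."""

    repetition_rate: float  # Hz
    n_bursts: int = 6
    burst_duration: float = 25.0  # ms
    burst_onsets: tuple = field(default=None)  # ms

    def __post_init__(self):
        if self.burst_onsets is None:
            onsets = tuple(k * 1000.0 / self.repetition_rate for k in range(self.n_bursts))
            object.__setattr__(self, "burst_onsets", onsets)
        if 1000.0 / self.repetition_rate <= self.burst_duration:
            raise ValueError("bursts overlap: period must exceed burst duration")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.repetition_rate

    @property
    def total_duration(self) -> float:
        """Onset of burst 1 through one full period after burst 6 onset (ms)."""
        return self.burst_onsets[-1] + self.period_ms


@dataclass
class SpeechStimulus:
    """A consonant-vowel speech token (synthetic proxy or loaded waveform)."""

    label: str
    waveform: np.ndarray
    sample_rate: float  # Hz
    consonant_window: tuple = (1.0, 40.0)  # ms from sound onset
    manner: str = "other"  # "stop" or "other"

    def __post_init__(self):
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("speech waveform contains non-finite samples")
        self.manner = "stop" if self.label in STOP_LABELS else "other"

    @property
    def total_duration(self) -> float:
        """Duration in ms."""
        return 1000.0 * len(self.waveform) / self.sample_rate


@dataclass(frozen=True)
class VNSTrain:
    """Vagus-nerve stimulation train: 500 ms, 16 biphasic pulses at 30 Hz."""

    duration: float = 500.0     # ms
    pulse_rate: float = 30.0    # Hz
    n_pulses: int = 16
    pulse_width: float = 100.0  # us, biphasic
    amplitude: float = 0.8      # mA

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("VNS amplitude must be positive")
        if (self.n_pulses - 1) * 1000.0 / self.pulse_rate > self.duration:
            raise ValueError("pulses do not fit within train duration")

    @property
    def pulse_times(self) -> np.ndarray:
        """Pulse onset times in ms (onset-inclusive)."""
        return np.arange(self.n_pulses) * 1000.0 / self.pulse_rate


@dataclass
class PairingSchedule:
    """One VNS-sound pairing session: event times and kinds.

    ``events`` is a list of ``(time_s, kind)`` with kind in {"pairing",
    "silence"}; times are sound onsets.  On pairing events the VNS train
    starts ``vns_lead`` ms before the sound.
    """

    session_duration: float  # s
    mean_iti: float          # s
    vns_lead: float          # ms
    events: list

    @property
    def pairing_times(self) -> np.ndarray:
        return np.array([t for t, k in self.events if k == "pairing"])

    @property
    def n_pairings(self) -> int:
        return sum(1 for _, k in self.events if k == "pairing")

    def vns_onset(self, sound_time_s: float) -> float:
        """VNS train onset (s) for a pairing whose sound starts at ``sound_time_s``."""
        return sound_time_s - self.vns_lead / 1000.0


# ---------------------------------------------------------------------------
# level calibration
# ---------------------------------------------------------------------------

def rms_level_db(segment: np.ndarray) -> float:
    """Level of a waveform segment in dB SPL under the package reference."""
    rms = math.sqrt(float(np.mean(np.square(segment, dtype=float))))
    if rms <= 0:
        return -np.inf
    return FULL_SCALE_SINE_DB + 20.0 * math.log10(rms / _REF_RMS)


def loudest_window_level(waveform: np.ndarray, sample_rate: float,
                         window: float = 100.0, hop: int = 1) -> float:
    """Maximum RMS level (dB SPL) over sliding windows of ``window`` ms.

    The search hop is one sample by default (exact); a coarser ``hop`` trades
    a sub-0.1 dB error for speed on long waveforms.
    """
    x = np.asarray(waveform, dtype=float)
    n_win = int(round(window * sample_rate / 1000.0))
    if n_win < 1 or n_win > len(x):
        raise ValueError("window longer than waveform")
    csum = np.concatenate(([0.0], np.cumsum(x * x)))
    starts = np.arange(0, len(x) - n_win + 1, hop)
    energy = csum[starts + n_win] - csum[starts]
    peak_rms = math.sqrt(float(energy.max()) / n_win)
    if peak_rms <= 0:
        return -np.inf
    return FULL_SCALE_SINE_DB + 20.0 * math.log10(peak_rms / _REF_RMS)


def calibrate_speech_level(waveform: np.ndarray, sample_rate: float,
                           target_level: float = 60.0, window: float = 100.0,
                           hop: int = 1):
    """Scale a waveform so its loudest ``window`` ms measures ``target_level`` dB SPL.

    Returns ``(scaled_waveform, scale_factor)``; the scale factor is a single
    positive multiplier.  Raises on silent input or a window longer than the
    waveform.
    """
    x = np.asarray(waveform, dtype=float)
    if not np.any(x != 0.0):
        raise ValueError("silent input: all-zero waveform cannot be calibrated")
    current = loudest_window_level(x, sample_rate, window=window, hop=hop)
    scale = 10.0 ** ((target_level - current) / 20.0)
    return x * scale, scale


# ---------------------------------------------------------------------------
# tone grid / noise trains / VNS
# ---------------------------------------------------------------------------

def make_tone_grid(freq_range=(1000.0, 32000.0), level_range=(0.0, 75.0),
                   n_freqs: int = 81, level_step: float = 5.0):
    """Log-spaced frequency x arithmetic level grid of 25 ms tone pips.

    Defaults give the conventional dense receptive-field grid: 81
    log-spaced frequencies over 1-32 kHz by 5 dB steps over 0-75 dB SPL
    (1296 tones).
    """
    f_lo, f_hi = freq_range
    l_lo, l_hi = level_range
    if f_lo >= f_hi or l_lo >= l_hi:
        raise ValueError("inverted frequency or level range")
    if n_freqs < 2:
        raise ValueError("n_freqs must be at least 2")
    freqs = np.geomspace(f_lo, f_hi, n_freqs)
    n_levels = int(math.floor((l_hi - l_lo) / level_step + 1e-9)) + 1
    levels = l_lo + level_step * np.arange(n_levels)
    return [ToneStimulus(frequency=float(f), level=float(l))
            for f in freqs for l in levels]


def make_noise_train(repetition_rate: float) -> NoiseBurstTrain:
    """Six-burst noise train at one of the supported repetition rates."""
    if repetition_rate not in NOISE_TRAIN_RATES:
        raise ValueError(
            f"unsupported repetition rate {repetition_rate}; "
            f"supported rates are {NOISE_TRAIN_RATES} Hz")
    return NoiseBurstTrain(repetition_rate=float(repetition_rate))


def make_vns_train() -> VNSTrain:
    return VNSTrain()


# ---------------------------------------------------------------------------
# pairing schedule
# ---------------------------------------------------------------------------

def _truncated_exp_scale(target_mean: float, lo: float, hi: float) -> float:
    """Scale of an exponential truncated to [lo, hi] with the given mean.

    Solved numerically so schedule ITIs average ``target_mean`` exactly
    despite the truncation.
    """
    span = hi - lo
    want = target_mean - lo
    # truncated-exponential mean spans (0, span/2) as the scale grows
    if not (0 < want < span / 2.0):
        raise ValueError("mean_iti not achievable inside the truncation bounds")

    def trunc_mean(beta):
        # E[X | X <= span] for X ~ Exp(beta)
        z = span / beta
        return beta - span * math.exp(-z) / (1.0 - math.exp(-z))

    return brentq(lambda b: trunc_mean(b) - want, 1e-6 * span, 1e3 * span)


def make_pairing_schedule(session_duration: float = 9000.0, mean_iti: float = 30.0,
                          seed: int = 0, vns_lead: float = 50.0,
                          iti_bounds=(10.0, 90.0), silence_fraction: float = 0.5,
                          iti_scope: str = "pairings") -> PairingSchedule:
    """Randomized VNS-sound pairing session schedule.

    Pairing-event inter-trial intervals are exponential with mean
    ``mean_iti`` s, truncated to ``iti_bounds`` (the underlying scale is
    adjusted so the truncated mean is exact).  A 9000 s session at a 30 s
    mean ITI therefore schedules ~300 pairings.  Silence catch trials are
    interleaved in a ``silence_fraction`` of the gaps, offset midway between
    pairings; with ``iti_scope="all"`` the ITI process instead governs the
    merged pairing+silence stream and pairings are the non-silence subset.
    """
    if session_duration <= 0 or mean_iti <= 0:
        raise ValueError("session_duration and mean_iti must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = iti_bounds
    beta = _truncated_exp_scale(mean_iti, lo, hi)
    span = hi - lo

    def draw_iti():
        # inverse-CDF sample of Exp(beta) truncated at span, shifted by lo
        u = rng.random()
        return lo + -beta * math.log1p(-u * (1.0 - math.exp(-span / beta)))

    events = []
    t = draw_iti()
    while t <= session_duration:
        if iti_scope == "all" and rng.random() < silence_fraction:
            events.append((t, "silence"))
        else:
            events.append((t, "pairing"))
        t += draw_iti()

    if iti_scope == "pairings" and silence_fraction > 0:
        # silence trials sit midway inside a random subset of the gaps
        silences = []
        times = [tt for tt, _ in events]
        for a, b in zip([0.0] + times[:-1], times):
            if rng.random() < silence_fraction:
                silences.append(((a + b) / 2.0, "silence"))
        events = sorted(events + silences)

    return PairingSchedule(session_duration=session_duration, mean_iti=mean_iti,
                           vns_lead=vns_lead, events=events)


# ---------------------------------------------------------------------------
# synthetic speech proxies
# ---------------------------------------------------------------------------

_VOWEL_FORMANTS = (700.0, 1200.0, 2600.0)  # /ae/-like, Hz (pre-shift rat range proxy)


def _label_onset_recipe(label: str):
    """Deterministic per-label onset signature: (center freqs Hz, bandwidth)."""
    idx = SPEECH_LABELS.index(label)
    rng = np.random.default_rng(7_654_321 + idx)
    centers = rng.uniform(1500.0, 12000.0, size=3)
    bw = rng.uniform(300.0, 1200.0)
    return centers, bw


def synth_speech_proxy(label: str, sample_rate: float = 44100.0, seed: int = 0,
                       target_level: float = 60.0) -> SpeechStimulus:
    """Synthetic consonant-vowel token standing in for recorded speech.

    A label-specific 40 ms onset (narrowband chirp complex for continuants,
    abrupt broadband burst for stop-initial tokens) is followed by a shared
    ~300 ms formant-like vowel plus a decay tail, then calibrated so the
    loudest 100 ms sits at ``target_level`` dB SPL.  Deterministic per
    ``(label, seed)``.
    """
    if label not in SPEECH_LABELS:
        raise ValueError(f"unknown speech label {label!r}; expected one of {SPEECH_LABELS}")
    rng = np.random.default_rng([seed, SPEECH_LABELS.index(label)])
    fs = sample_rate
    t_onset = np.arange(int(0.040 * fs)) / fs
    centers, bw = _label_onset_recipe(label)

    onset = np.zeros_like(t_onset)
    for c in centers:
        onset += np.sin(2 * np.pi * c * t_onset + rng.uniform(0, 2 * np.pi))
    onset *= np.exp(-t_onset / 0.015)
    if label in STOP_LABELS:
        # abrupt broadband release burst in the first 10 ms
        burst = rng.standard_normal(len(t_onset)) * np.exp(-t_onset / 0.004)
        onset = onset * 0.4 + burst * 1.5
    else:
        # slower frication/sonorant ramp
        onset *= 1.0 - np.exp(-t_onset / 0.010)
        onset += 0.2 * rng.standard_normal(len(t_onset)) * np.exp(-t_onset / (bw / 1e5))

    t_vowel = np.arange(int(0.310 * fs)) / fs
    f0 = 180.0
    vowel = np.zeros_like(t_vowel)
    for k, (f_c, w) in enumerate(zip(_VOWEL_FORMANTS, (1.0, 0.6, 0.3))):
        vowel += w * np.sin(2 * np.pi * f_c * t_vowel)
    vowel *= 0.5 * (1.0 + np.sin(2 * np.pi * f0 * t_vowel))  # glottal-pulse-like AM
    vowel *= np.minimum(t_vowel / 0.02, 1.0)
    tail = np.exp(-np.arange(int(0.060 * fs)) / fs / 0.02)
    vowel = np.concatenate([vowel, vowel[-1] * tail * np.sin(
        2 * np.pi * _VOWEL_FORMANTS[0] * (t_vowel[-1] + np.arange(len(tail)) / fs))])

    wave = np.concatenate([onset, vowel])
    wave, _ = calibrate_speech_level(wave, fs, target_level=target_level)
    return SpeechStimulus(label=label, waveform=wave, sample_rate=fs)
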