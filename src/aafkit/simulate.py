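"""Synthetic nested-cohort multi-unit spike-response simulator.

Generates trial-tagged spike timestamps with the statistical structure the
downstream analysis assumes: nested animal/site random effects on gain,
inhomogeneous-Poisson spiking (spontaneous background plus alpha-kernel
evoked bumps), Gaussian frequency tuning with a saturating rate-level
function for tones, per-burst adaptation and odd-burst suppression for noise
trains, and label-conditional onset patterns plus a sustained vowel response
for speech.

Sampling is exact: by Poisson superposition, each evoked bump contributes a
Poisson-distributed spike count equal to its integrated rate, with spike
times drawn from the normalized kernel.  The alpha kernel
``(t/tau) * exp(1 - t/tau)`` is the Gamma(shape=2, scale=tau) density up to
scale, so bump spike times are Gamma draws; spontaneous spikes are a
homogeneous Poisson process over the analysis window.  This yields the same
point-process law as thinning at a fraction of the cost.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

from .presets import GroupEffectConfig, PRESETS
from .stimuli import (NoiseBurstTrain, SpeechStimulus, ToneStimulus,
                      SPEECH_LABELS)

__all__ = [
    "RecordingSite",
    "SpikeResponseSet",
    "RESPONSE_WINDOW",
    "realize_cohort",
    "simulate_tone_response",
    "simulate_tone_grid",
    "simulate_train_response",
    "simulate_speech_response",
    "tone_evoked_amplitude",
]

#: spike-time analysis window relative to stimulus onset, ms
RESPONSE_WINDOW = (-100.0, 750.0)

ALPHA_TAU = 5.0          # ms, default alpha-kernel time constant
SPEECH_ONSET_TAU = 2.0   # ms, sharper kernel for consonant onsets
TONE_AMP_MAX = 3.0       # expected driven spikes/tone at CF, 75 dB, gain 1
TRAIN_AMP = 3.0          # expected driven spikes for burst 1 at gain 1
SPEECH_ONSET_AMP = 3.0   # expected consonant-onset spikes at gain 1
SPEECH_VOWEL_AMP = 4.0   # expected sustained vowel spikes at vowel_gain 1
VOWEL_SPAN = (60.0, 400.0)  # ms, sustained vowel response support


@dataclass(frozen=True)
class RecordingSite:
    """Per-site realization of tuning and nested random effects."""

    site_id: str
    animal_id: str
    group: str
    cf: float              # Hz
    threshold: float       # dB SPL
    tuning_width: float    # octaves (Gaussian SD in log2 frequency)
    latency: float         # ms onset latency (group shift already applied)
    gain: float            # realized evoked-rate multiplier
    config: GroupEffectConfig

    def __post_init__(self):
        if not (1000.0 <= self.cf <= 32000.0):
            raise ValueError("CF outside [1, 32] kHz")
        if not (0.0 <= self.threshold <= 75.0):
            raise ValueError("threshold outside [0, 75] dB")


@dataclass
class SpikeResponseSet:
    """Trial-tagged spike times for one site x one stimulus (20 repeats)."""

    site_id: str
    stimulus_id: str
    trials: list  # list of sorted float arrays, ms relative to stimulus onset
    window: tuple = RESPONSE_WINDOW

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def pooled(self) -> np.ndarray:
        """All spike times pooled over trials."""
        if not self.trials:
            return np.empty(0)
        return np.concatenate([np.asarray(t, dtype=float) for t in self.trials])

    def counts_in(self, t0: float, t1: float) -> np.ndarray:
        """Per-trial spike counts in [t0, t1)."""
        return np.array([np.count_nonzero((t >= t0) & (t < t1)) for t in self.trials])


# ---------------------------------------------------------------------------
# core sampler
# ---------------------------------------------------------------------------

def _sample_trials(rng, n_trials, spont_rate, bumps=(), uniforms=(),
                   window=RESPONSE_WINDOW):
    """Exact inhomogeneous-Poisson trials by superposition.

    ``bumps``: iterable of (onset_ms, expected_spikes, tau_ms, jitter_sd_ms)
    alpha-kernel components.  ``uniforms``: (t0, t1, expected_spikes)
    homogeneous segments (sustained responses).  Returns a list of sorted
    spike-time arrays.
    """
    t0, t1 = window
    parts_t, parts_i = [], []

    c = rng.poisson(spont_rate * (t1 - t0) / 1000.0, n_trials)
    parts_t.append(rng.uniform(t0, t1, int(c.sum())))
    parts_i.append(np.repeat(np.arange(n_trials), c))

    for onset, amp, tau, jitter in bumps:
        if amp <= 0:
            continue
        c = rng.poisson(amp, n_trials)
        n = int(c.sum())
        tt = onset + rng.gamma(2.0, tau, n)
        if jitter > 0:
            tt = tt + rng.normal(0.0, jitter, n)
        parts_t.append(tt)
        parts_i.append(np.repeat(np.arange(n_trials), c))

    for a, b, amp in uniforms:
        if amp <= 0:
            continue
        c = rng.poisson(amp, n_trials)
        n = int(c.sum())
        parts_t.append(rng.uniform(a, b, n))
        parts_i.append(np.repeat(np.arange(n_trials), c))

    t = np.concatenate(parts_t)
    i = np.concatenate(parts_i)
    keep = (t >= t0) & (t <= t1)
    t, i = t[keep], i[keep]
    order = np.lexsort((t, i))
    t, i = t[order], i[order]
    splits = np.searchsorted(i, np.arange(1, n_trials))
    return np.split(t, splits)


# ---------------------------------------------------------------------------
# cohort realization
# ---------------------------------------------------------------------------

def realize_cohort(configs=None, n_animals: int = 10, sites_per_animal: int = 30,
                   seed: int = 0, threshold_range=(10.0, 30.0),
                   threshold_step: float = 5.0, tuning_width: float = 0.5):
    """Draw a nested cohort of recording sites for each group config.

    Site log-gain = log(group gain) + N(0, animal_sd) per animal
    + N(0, site_sd) per site.  CFs are log-uniform on 1-32 kHz, thresholds
    uniform on the level grid within ``threshold_range``, and onset latencies
    normal around ``base_latency + latency_shift``.
    """
    if configs is None:
        configs = list(PRESETS.values())
    if isinstance(configs, GroupEffectConfig):
        configs = [configs]
    if n_animals < 1 or sites_per_animal < 1:
        raise ValueError("counts must be >= 1")

    rng = np.random.default_rng(seed)
    sites = []
    for cfg in configs:
        for a in range(n_animals):
            animal_id = f"{cfg.group}-a{a:02d}"
            animal_eff = rng.normal(0.0, cfg.animal_sd) if cfg.animal_sd > 0 else 0.0
            for s in range(sites_per_animal):
                site_eff = rng.normal(0.0, cfg.site_sd) if cfg.site_sd > 0 else 0.0
                gain = cfg.gain * math.exp(animal_eff + site_eff)
                cf = float(np.exp(rng.uniform(np.log(1000.0), np.log(32000.0))))
                n_steps = int(round((threshold_range[1] - threshold_range[0])
                                    / threshold_step))
                thr = threshold_range[0] + threshold_step * rng.integers(0, n_steps + 1)
                lat = cfg.base_latency + cfg.latency_shift
                if cfg.latency_site_sd > 0:
                    lat += rng.normal(0.0, cfg.latency_site_sd)
                lat = max(lat, 8.0)
                sites.append(RecordingSite(
                    site_id=f"{animal_id}-s{s:03d}", animal_id=animal_id,
                    group=cfg.group, cf=cf, threshold=float(thr),
                    tuning_width=tuning_width, latency=lat, gain=gain,
                    config=cfg))
    return sites


# ---------------------------------------------------------------------------
# tone responses
# ---------------------------------------------------------------------------

def tone_evoked_amplitude(site: RecordingSite, frequency: float, level: float,
                          amp_max: float = TONE_AMP_MAX) -> float:
    """Expected driven spikes/trial for one tone: Gaussian log-frequency
    tuning around CF times a saturating rate-level term above threshold."""
    d_oct = math.log2(frequency / site.cf)
    tune = math.exp(-0.5 * (d_oct / site.tuning_width) ** 2)
    if level < site.threshold:
        rl = 0.0
    else:
        rl = 1.0 - math.exp(-(level - site.threshold + 5.0) / 20.0)
    return site.gain * amp_max * tune * rl


def simulate_tone_response(site: RecordingSite, tone: ToneStimulus, seed: int = 0,
                           n_trials: int = 20, rng=None) -> SpikeResponseSet:
    """20 Poisson trials of the response to one tone pip."""
    if rng is None:
        rng = np.random.default_rng(seed)
    amp = tone_evoked_amplitude(site, tone.frequency, tone.level)
    bumps = [(site.latency, amp, ALPHA_TAU, 0.0)]
    trials = _sample_trials(rng, n_trials, site.config.spont_rate, bumps=bumps)
    stim_id = f"tone_{tone.frequency:.0f}Hz_{tone.level:.0f}dB"
    return SpikeResponseSet(site_id=site.site_id, stimulus_id=stim_id, trials=trials)


def simulate_tone_grid(site: RecordingSite, tones, seed: int = 0,
                       n_trials: int = 20):
    """Responses to a full tone grid, keyed by (frequency, level)."""
    rng = np.random.default_rng([seed, zlib.crc32(site.site_id.encode())])
    out = {}
    for tone in tones:
        out[(tone.frequency, tone.level)] = simulate_tone_response(
            site, tone, n_trials=n_trials, rng=rng)
    return out


# ---------------------------------------------------------------------------
# noise-train responses
# ---------------------------------------------------------------------------

def simulate_train_response(site: RecordingSite, train: NoiseBurstTrain,
                            seed: int = 0, n_trials: int = 20, rng=None,
                            amp: float = TRAIN_AMP) -> SpikeResponseSet:
    """20 trials of the response to a six-burst noise train.

    Burst k (1-based) evokes an alpha bump of amplitude
    ``gain * adaptation^(k-1) * odd_burst_suppression``(for k in {3, 5}),
    with spike times jittered by the group's phase_jitter SD.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cfg = site.config
    bumps = []
    for k, onset in enumerate(train.burst_onsets, start=1):
        a = site.gain * amp * cfg.adaptation ** (k - 1)
        if k in (3, 5):
            a *= cfg.odd_burst_suppression
        bumps.append((onset + site.latency, a, ALPHA_TAU, cfg.phase_jitter))
    trials = _sample_trials(rng, n_trials, cfg.spont_rate, bumps=bumps)
    stim_id = f"train_{train.repetition_rate:g}Hz"
    return SpikeResponseSet(site_id=site.site_id, stimulus_id=stim_id, trials=trials)


# ---------------------------------------------------------------------------
# speech responses
# ---------------------------------------------------------------------------

def _label_pattern(label: str):
    """Fixed label-specific onset micro-pattern: (latencies ms, weights)."""
    idx = SPEECH_LABELS.index(label)
    rng = np.random.default_rng(1_234_500 + idx)
    lat = np.sort(rng.uniform(0.0, 20.0, 3))
    w = rng.dirichlet(np.ones(3))
    return lat, w


_COMMON_PATTERN = (np.array([5.0, 10.0, 15.0]), np.array([0.3, 0.4, 0.3]))


def _onset_bumps(site: RecordingSite, label: str, separability: float,
                 onset_gain: float):
    """Consonant-onset sub-bumps interpolated between a shared pattern and
    the label-specific one by the separability parameter."""
    lat_l, w_l = _label_pattern(label)
    lat_c, w_c = _COMMON_PATTERN
    s = float(np.clip(separability, 0.0, 1.0))
    lat = (1 - s) * lat_c + s * lat_l
    w = (1 - s) * w_c + s * w_l
    w = w / w.sum()
    total = onset_gain * SPEECH_ONSET_AMP
    return [(site.latency + float(l), total * float(wi), SPEECH_ONSET_TAU, 0.5)
            for l, wi in zip(lat, w)]


def simulate_speech_response(site: RecordingSite, speech: SpeechStimulus,
                             seed: int = 0, n_trials: int = 20, rng=None,
                             onset_gain: float = None, vowel_gain: float = None,
                             separability: float = None) -> SpikeResponseSet:
    """20 trials of the response to a consonant-vowel speech token.

    A label-conditional cluster of onset bumps inside the 1-40 ms consonant
    window is followed by a sustained vowel response out to 400 ms.  The
    group gain and latency effects apply to the onset; the vowel has its own
    gain.  With separability 0 every label shares one response distribution.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cfg = site.config
    if onset_gain is None:
        onset_gain = site.gain
    if vowel_gain is None:
        vowel_gain = cfg.vowel_gain * site.gain / cfg.gain  # site RE, group vowel gain
    if separability is None:
        separability = cfg.separability
    bumps = _onset_bumps(site, speech.label, separability, onset_gain)
    uniforms = [(VOWEL_SPAN[0], VOWEL_SPAN[1], vowel_gain * SPEECH_VOWEL_AMP)]
    trials = _sample_trials(rng, n_trials, cfg.spont_rate, bumps=bumps,
                            uniforms=uniforms)
    return SpikeResponseSet(site_id=site.site_id,
                            stimulus_id=f"speech_{speech.label}", trials=trials)
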