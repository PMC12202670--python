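"""Speech-window response measures and the nearest-template neural classifier.

Measures spont-corrected driven activity in the consonant onset window
(1-40 ms), the vowel window (default 40-340 ms), and the full 0-400 ms
token, plus PSTH onset/peak latency, and implements the leave-one-out
nearest-template classifier: each held-out trial is binned (1 ms default)
over the classification window and assigned to the label whose mean-PSTH
template (19 remaining same-label trials vs all 20 other-label trials) is
closer in Euclidean distance; chance is 50% for a pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .receptive_field import estimate_latencies
from .simulate import SpikeResponseSet

__all__ = [
    "SpeechResponseSummary",
    "ClassifierResult",
    "CONSONANT_WINDOW",
    "VOWEL_WINDOW",
    "FULL_WINDOW",
    "speech_window_activity",
    "loo_template_classifier",
    "stop_consonant_panel",
    "STOP_PAIRS",
]

CONSONANT_WINDOW = (1.0, 40.0)   # ms from sound onset
VOWEL_WINDOW = (40.0, 340.0)     # ms, 300 ms vowel segment
FULL_WINDOW = (0.0, 400.0)       # ms, entire token

STOP_PAIRS = tuple(itertools.combinations(("bad", "dad", "gad", "tad"), 2))


@dataclass
class SpeechResponseSummary:
    site_id: str
    label: str
    consonant_activity: float  # driven spikes/trial, 1-40 ms
    vowel_activity: float      # driven spikes/trial, vowel window
    full_activity: float       # driven spikes/trial, 0-400 ms
    onset_latency: float
    peak_latency: float


@dataclass
class ClassifierResult:
    site_id: str
    pair: tuple
    percent_correct: float
    confusion: np.ndarray      # 2x2 counts, rows true label, cols assigned
    n_trials_scored: int

    def __post_init__(self):
        total = int(self.confusion.sum())
        if total != self.n_trials_scored:
            raise ValueError("confusion counts do not sum to trials scored")


def _spont_rate(responses: SpikeResponseSet) -> float:
    pre = [np.count_nonzero((t >= -100.0) & (t < 0.0)) for t in responses.trials]
    return float(np.sum(pre)) / (responses.n_trials * 0.1)


def speech_window_activity(responses: SpikeResponseSet, label: str = None,
                           consonant_window=CONSONANT_WINDOW,
                           vowel_window=VOWEL_WINDOW,
                           full_window=FULL_WINDOW,
                           spont_rate: float = None) -> SpeechResponseSummary:
    """Spont-corrected window activities and PSTH latencies for one token."""
    if spont_rate is None:
        spont_rate = _spont_rate(responses)

    def driven(window):
        w0, w1 = window
        expected = spont_rate * (w1 - w0) / 1000.0
        return float(np.mean(responses.counts_in(w0, w1))) - expected

    onset, peak = estimate_latencies([responses], spont_rate=spont_rate)
    if label is None:
        label = responses.stimulus_id.removeprefix("speech_")
    return SpeechResponseSummary(
        site_id=responses.site_id, label=label,
        consonant_activity=driven(consonant_window),
        vowel_activity=driven(vowel_window),
        full_activity=driven(full_window),
        onset_latency=onset, peak_latency=peak)


def _bin_trials(trials, window, bin_ms):
    edges = np.arange(window[0], window[1] + bin_ms / 2.0, bin_ms)
    return np.stack([np.histogram(t, bins=edges)[0] for t in trials]).astype(float)


def loo_template_classifier(responses_a: SpikeResponseSet,
                            responses_b: SpikeResponseSet,
                            bin_ms: float = 1.0, window=(0.0, 40.0),
                            seed: int = 0, rng=None) -> ClassifierResult:
    """Leave-one-out nearest-template classification of a label pair.

    Requires exactly 20 trials per label.  For each of the 40 folds the
    held-out trial's binned spike vector is compared to the same-label
    template (mean over the remaining 19 trials) and the other label's
    template (all 20 trials); ties are broken by a seeded coin flip.
    """
    if responses_a.n_trials != responses_b.n_trials:
        raise ValueError("unequal trial counts between labels")
    if responses_a.n_trials != 20:
        raise ValueError("classifier requires exactly 20 trials per label")
    if window[1] <= window[0]:
        raise ValueError("empty classification window")
    if rng is None:
        rng = np.random.default_rng(seed)

    xa = _bin_trials(responses_a.trials, window, bin_ms)
    xb = _bin_trials(responses_b.trials, window, bin_ms)
    n = xa.shape[0]
    sum_a, sum_b = xa.sum(axis=0), xb.sum(axis=0)
    mean_a, mean_b = sum_a / n, sum_b / n

    confusion = np.zeros((2, 2), dtype=int)
    for true_idx, (x, own_sum, other_mean) in enumerate(
            ((xa, sum_a, mean_b), (xb, sum_b, mean_a))):
        for i in range(n):
            own_template = (own_sum - x[i]) / (n - 1)
            d_own = float(np.sum((x[i] - own_template) ** 2))
            d_other = float(np.sum((x[i] - other_mean) ** 2))
            if d_own < d_other:
                assigned = true_idx
            elif d_other < d_own:
                assigned = 1 - true_idx
            else:
                assigned = int(rng.integers(0, 2))
            confusion[true_idx, assigned] += 1

    n_scored = 2 * n
    correct = confusion[0, 0] + confusion[1, 1]
    label_a = responses_a.stimulus_id.removeprefix("speech_")
    label_b = responses_b.stimulus_id.removeprefix("speech_")
    return ClassifierResult(site_id=responses_a.site_id, pair=(label_a, label_b),
                            percent_correct=100.0 * correct / n_scored,
                            confusion=confusion, n_trials_scored=n_scored)


def stop_consonant_panel(responses_by_label: dict, bin_ms: float = 1.0,
                         window=(0.0, 40.0), seed: int = 0):
    """Mean percent-correct over the six stop-consonant pairs for one site.

    ``responses_by_label`` maps token labels to :class:`SpikeResponseSet`;
    the four stop-initial tokens must be present.  Returns
    ``(mean_percent_correct, list_of_ClassifierResult)``.
    """
    missing = [l for pair in STOP_PAIRS for l in pair
               if l not in responses_by_label]
    if missing:
        raise ValueError(f"missing stop-consonant tokens: {sorted(set(missing))}")
    rng = np.random.default_rng(seed)
    results = [loo_template_classifier(responses_by_label[a], responses_by_label[b],
                                       bin_ms=bin_ms, window=window, rng=rng)
               for a, b in STOP_PAIRS]
    return float(np.mean([r.percent_correct for r in results])), results
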