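"""End-to-end synthetic-cohort pipeline.

Simulates a nested cohort per group preset, runs every analysis stage
(receptive fields from a tone grid, temporal metrics from the four noise
trains, speech-window measures and the stop-consonant classifier panel), and
tabulates per-site metrics plus per-group means.  This is the surface the
qualitative group-ordering checks and the CLI drive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import receptive_field as rf
from . import speech as sp
from . import temporal as tm
from .presets import PRESETS
from .simulate import (realize_cohort, simulate_speech_response,
                       simulate_tone_grid, simulate_train_response)
from .stimuli import (NOISE_TRAIN_RATES, SPEECH_LABELS, make_noise_train,
                      make_tone_grid, synth_speech_proxy)

__all__ = ["run_cohort_pipeline", "group_summary"]

STOP_LABELS_PANEL = ("bad", "dad", "gad", "tad")


def run_cohort_pipeline(seed: int = 0, configs=None, n_animals: int = 4,
                        sites_per_animal: int = 6, n_freqs: int = 25,
                        level_step: float = 5.0, speech_labels=STOP_LABELS_PANEL,
                        suprathreshold_level: float = 40.0) -> pd.DataFrame:
    """Simulate and analyze one cohort per group config.

    Returns a per-site DataFrame: group, animal, site, receptive-field
    metrics (cf, threshold, onset/peak latency, suprathreshold rate-level
    mean), temporal metrics averaged over the four repetition rates
    (steady-state rate, vector strength, phase-locked fraction, PPR), speech
    consonant/vowel activity averaged over stop tokens, and the
    stop-consonant classifier mean percent correct.  Non-responsive sites are
    carried with NaN metrics and ``responsive = False``.
    """
    if configs is None:
        configs = list(PRESETS.values())
    sites = realize_cohort(configs, n_animals=n_animals,
                           sites_per_animal=sites_per_animal, seed=seed)
    tones = make_tone_grid(n_freqs=n_freqs, level_step=level_step)
    trains = [make_noise_train(r) for r in NOISE_TRAIN_RATES]
    speech_tokens = {lbl: synth_speech_proxy(lbl, seed=seed)
                     for lbl in speech_labels}

    rows = []
    for i, site in enumerate(sites):
        rng = np.random.default_rng([seed, 1000 + i])
        row = {"site": site.site_id, "animal": site.animal_id,
               "group": site.group, "responsive": True}

        grid = simulate_tone_grid(site, tones, seed=seed)
        try:
            summ = rf.summarize_site(site.site_id, grid)
            row.update(cf=summ.cf, threshold=summ.threshold,
                       onset_latency=summ.onset_latency,
                       peak_latency=summ.peak_latency,
                       spont_rate=summ.spont_rate,
                       bw20=summ.bw20,
                       driven_near_cf=summ.driven_spikes_near_cf,
                       rate_level_supra=float(np.mean(
                           [v for l, v in summ.rate_level.items()
                            if l >= suprathreshold_level])))
        except rf.NonResponsiveSite:
            row["responsive"] = False
            rows.append(row)
            continue

        t_sum = []
        for train in trains:
            resp = simulate_train_response(site, train, rng=rng)
            t_sum.append(tm.summarize_train_response(resp, train))
        row.update(
            steady_state=float(np.mean([t.steady_state_rate for t in t_sum])),
            vector_strength=float(np.nanmean([t.vector_strength for t in t_sum])),
            phase_locked_fraction=float(np.mean([t.phase_locked for t in t_sum])),
            ppr=float(np.nanmean([t.ppr for t in t_sum])))

        speech_resp = {lbl: simulate_speech_response(site, tok, rng=rng)
                       for lbl, tok in speech_tokens.items()}
        acts = [sp.speech_window_activity(r, label=lbl)
                for lbl, r in speech_resp.items()]
        row.update(
            consonant_activity=float(np.mean([a.consonant_activity for a in acts])),
            vowel_activity=float(np.mean([a.vowel_activity for a in acts])),
            full_activity=float(np.mean([a.full_activity for a in acts])))
        pct, _ = sp.stop_consonant_panel(speech_resp, seed=seed)
        row["classifier_pct"] = pct
        rows.append(row)
    return pd.DataFrame(rows)


def group_summary(site_table: pd.DataFrame) -> pd.DataFrame:
    """Per-group means of every numeric pipeline metric (responsive sites)."""
    resp = site_table[site_table["responsive"]]
    return resp.groupby("group").mean(numeric_only=True)
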