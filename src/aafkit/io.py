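"""Serialization: HDF5 spike datasets, flat CSV export, WAV stimuli.

HDF5 layout::

    /cohort                      site manifest (one dataset per column)
    /responses/{site}/{stim}     variable-length array, one row per trial

Spike times are milliseconds relative to stimulus onset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import RecordingSite, SpikeResponseSet
from .presets import GroupEffectConfig

__all__ = [
    "cohort_manifest",
    "save_responses_h5",
    "load_responses_h5",
    "responses_to_csv",
    "write_wav",
]


def cohort_manifest(sites) -> pd.DataFrame:
    """Tabular manifest of a realized cohort."""
    return pd.DataFrame([{
        "site_id": s.site_id, "animal_id": s.animal_id, "group": s.group,
        "cf_hz": s.cf, "threshold_db": s.threshold,
        "tuning_width_oct": s.tuning_width, "latency_ms": s.latency,
        "gain": s.gain} for s in sites])


def save_responses_h5(path, sites, responses):
    """Write a cohort and its responses.

    ``responses``: ``{site_id: {stimulus_id: SpikeResponseSet}}``.
    """
    import h5py
    manifest = cohort_manifest(sites)
    with h5py.File(path, "w") as f:
        g = f.create_group("cohort")
        for col in manifest.columns:
            data = manifest[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)
        vlen = h5py.special_dtype(vlen=np.dtype("float64"))
        root = f.create_group("responses")
        for site_id, by_stim in responses.items():
            gs = root.create_group(site_id)
            for stim_id, rs in by_stim.items():
                ds = gs.create_dataset(stim_id, (rs.n_trials,), dtype=vlen)
                for i, t in enumerate(rs.trials):
                    ds[i] = np.asarray(t, dtype=float)
                ds.attrs["window"] = rs.window


def load_responses_h5(path):
    """Read back ``(manifest_df, {site_id: {stim_id: SpikeResponseSet}})``."""
    import h5py
    with h5py.File(path, "r") as f:
        cols = {}
        for col, ds in f["cohort"].items():
            arr = ds[()]
            if arr.dtype.kind == "S":
                arr = arr.astype(str)
            cols[col] = arr
        manifest = pd.DataFrame(cols)
        responses = {}
        for site_id, gs in f["responses"].items():
            by_stim = {}
            for stim_id, ds in gs.items():
                trials = [np.asarray(row, dtype=float) for row in ds[()]]
                by_stim[stim_id] = SpikeResponseSet(
                    site_id=site_id, stimulus_id=stim_id, trials=trials,
                    window=tuple(ds.attrs.get("window", (-100.0, 750.0))))
            responses[site_id] = by_stim
    return manifest, responses


def responses_to_csv(path, sites, responses):
    """Flat per-spike CSV: site, animal, group, stimulus, trial, spike_time_ms."""
    lookup = {s.site_id: s for s in sites}
    rows = []
    for site_id, by_stim in responses.items():
        s = lookup[site_id]
        for stim_id, rs in by_stim.items():
            for trial, times in enumerate(rs.trials):
                for t in np.asarray(times, dtype=float):
                    rows.append((site_id, s.animal_id, s.group, stim_id,
                                 trial, t))
    df = pd.DataFrame(rows, columns=["site", "animal", "group", "stimulus",
                                     "trial", "spike_time_ms"])
    df.to_csv(path, index=False)
    return df


def write_wav(path, waveform, sample_rate):
    """Write a float waveform as 32-bit float WAV (scipy backend)."""
    from scipy.io import wavfile
    wavfile.write(path, int(sample_rate), np.asarray(waveform, dtype=np.float32))
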