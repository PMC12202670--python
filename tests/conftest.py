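import numpy as np
import pytest

from aafkit.presets import preset
from aafkit.simulate import SpikeResponseSet, realize_cohort
from aafkit.stimuli import synth_speech_proxy


@pytest.fixture(scope="session")
def stop_tokens():
    """The four stop-consonant-initial synthetic speech tokens."""
    return {l: synth_speech_proxy(l, seed=0) for l in ("bad", "dad", "gad", "tad")}


@pytest.fixture
def sal_site():
    """One saline-like recording site with fixed tuning."""
    return realize_cohort(preset("SAL"), n_animals=1, sites_per_animal=1, seed=7)[0]


def make_response(trials, site_id="s0", stimulus_id="stim"):
    """Wrap raw per-trial spike-time lists into a SpikeResponseSet."""
    return SpikeResponseSet(site_id=site_id, stimulus_id=stimulus_id,
                            trials=[np.asarray(t, dtype=float) for t in trials])
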