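"""Go/no-go operant session scoring and behavioral group statistics.

Sessions are streams of target and silence/non-target catch trials plus
nose-poke timestamps.  A poke inside a target trial's hit window is a hit;
a poke during a catch trial, or any poke outside a valid hit window,
triggers a 6 s timeout during which further pokes are ignored.  Percent
correct = (hits + correct rejections) / trials.  Weekly percent-correct
curves are compared with a two-way mixed-design repeated-measures ANOVA
(training week within animal, exposure group between animals) with
Bonferroni-corrected post hocs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BehaviorSession",
    "score_go_nogo",
    "proficiency_reached",
    "success_paired_vns_log",
    "rm_anova",
    "simulate_agent_session",
    "simulate_learning_curves",
]

TIMEOUT_S = 6.0
PROFICIENCY_CRITERION = 75.0
PROFICIENCY_SESSIONS = 4


@dataclass
class BehaviorSession:
    trials: list                 # (time_s, kind, outcome) after scoring
    hit_window: float            # s, 3 or 4
    percent_correct: float
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    n_timeouts: int
    session_index: int = 0
    rewarded_hit_times: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def score_go_nogo(trials, pokes, hit_window: float = 3.0,
                  timeout: float = TIMEOUT_S, session_index: int = 0) -> BehaviorSession:
    """Score one go/no-go session.

    ``trials``: time-ordered ``(onset_s, kind)`` with kind in {"target",
    "nontarget", "silence"}; ``pokes``: nose-poke times (s).  Hit windows
    must not overlap.  Pokes arriving during a timeout are ignored; a poke
    on a catch trial or outside any open hit window is a false alarm and
    starts a ``timeout`` s timeout.
    """
    trials = sorted(trials, key=lambda t: t[0])
    for (t0, _), (t1, _) in zip(trials, trials[1:]):
        if t1 < t0 + hit_window:
            raise ValueError("overlapping trials: hit windows intersect")
    if hit_window not in (3.0, 4.0):
        # protocol uses 4 s early in training, 3 s later; other values are
        # allowed but unusual
        pass

    outcome = [None] * len(trials)
    onsets = np.array([t for t, _ in trials])
    kinds = [k for _, k in trials]
    timeout_until = -np.inf
    n_timeouts = 0
    rewarded = []

    for p in sorted(pokes):
        if p < timeout_until:
            continue  # booth dark, poke elicits no feedback
        idx = int(np.searchsorted(onsets, p, side="right")) - 1
        in_window = idx >= 0 and p <= onsets[idx] + hit_window
        if in_window and kinds[idx] == "target":
            if outcome[idx] is None:
                outcome[idx] = "hit"
                rewarded.append(p)
            continue  # extra pokes inside an already-rewarded window: no-op
        if in_window and outcome[idx] is None:
            outcome[idx] = "false_alarm"
        timeout_until = p + timeout
        n_timeouts += 1

    for i, k in enumerate(kinds):
        if outcome[i] is None:
            outcome[i] = "miss" if k == "target" else "correct_rejection"

    hits = outcome.count("hit")
    misses = outcome.count("miss")
    fas = outcome.count("false_alarm")
    crs = outcome.count("correct_rejection")
    pct = 100.0 * (hits + crs) / len(trials) if trials else float("nan")
    scored = [(t, k, o) for (t, k), o in zip(trials, outcome)]
    return BehaviorSession(trials=scored, hit_window=hit_window,
                           percent_correct=pct, hits=hits, misses=misses,
                           false_alarms=fas, correct_rejections=crs,
                           n_timeouts=n_timeouts, session_index=session_index,
                           rewarded_hit_times=rewarded)


def proficiency_reached(sessions, criterion: float = PROFICIENCY_CRITERION,
                        n_required: int = PROFICIENCY_SESSIONS) -> bool:
    """True once ``n_required`` consecutive sessions reach ``criterion`` %."""
    run = 0
    for s in sessions:
        run = run + 1 if s.percent_correct >= criterion else 0
        if run >= n_required:
            return True
    return False


def success_paired_vns_log(sessions):
    """Per-session VNS stimulation counts: one stimulation per rewarded hit."""
    return [s.hits for s in sessions]


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def rm_anova(data: pd.DataFrame, dv: str = "percent_correct",
             within: str = "week", between: str = "group",
             subject: str = "animal", gg_correction: bool = False):
    """Two-way mixed repeated-measures ANOVA with Bonferroni post hocs.

    ``data`` is long-format with one row per animal x week.  Requires
    balanced weeks within animal.  Returns ``(anova_table, posthoc_table)``;
    on degenerate (constant) data the table carries a ``degenerate`` flag
    instead of crashing.
    """
    counts = data.groupby(subject)[within].nunique()
    if counts.nunique() != 1:
        raise ValueError("unbalanced weeks within animal")
    if np.isclose(float(data[dv].var()), 0.0):
        tab = pd.DataFrame({"Source": [between, within, "Interaction"],
                            "F": [np.nan] * 3, "p": [np.nan] * 3})
        tab.attrs["degenerate"] = True
        return tab, pd.DataFrame()

    import pingouin as pg
    tab = pg.mixed_anova(data=data, dv=dv, within=within, between=between,
                         subject=subject, correction=gg_correction)
    pcol = "p_unc" if "p_unc" in tab.columns else "p-unc"
    tab = tab.rename(columns={pcol: "p"})
    tab.attrs["degenerate"] = False

    # Bonferroni-corrected pairwise group comparisons on animal means
    means = data.groupby([subject, between])[dv].mean().reset_index()
    groups = sorted(means[between].unique())
    pairs = list(itertools.combinations(groups, 2))
    rows = []
    for a, b in pairs:
        xa = means.loc[means[between] == a, dv]
        xb = means.loc[means[between] == b, dv]
        t, p = sps.ttest_ind(xa, xb)
        rows.append({"contrast": f"{a} - {b}", "t": float(t),
                     "p_bonf": float(min(p * len(pairs), 1.0))})
    return tab, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic sessions and learning curves
# ---------------------------------------------------------------------------

def simulate_agent_session(seed: int = 0, n_trials: int = 100,
                           target_fraction: float = 0.5, p_hit: float = 0.8,
                           p_false_alarm: float = 0.1, hit_window: float = 3.0,
                           iti: float = 10.0):
    """Generate one session's trials and pokes from a probabilistic agent.

    The agent pokes within the hit window on a fraction ``p_hit`` of target
    trials (uniform reaction time) and on ``p_false_alarm`` of catch trials.
    Returns ``(trials, pokes)`` ready for :func:`score_go_nogo`.
    """
    rng = np.random.default_rng(seed)
    trials, pokes = [], []
    t = 5.0
    for _ in range(n_trials):
        kind = "target" if rng.random() < target_fraction else "silence"
        trials.append((t, kind))
        if kind == "target" and rng.random() < p_hit:
            pokes.append(t + rng.uniform(0.2, hit_window * 0.9))
        elif kind != "target" and rng.random() < p_false_alarm:
            pokes.append(t + rng.uniform(0.2, hit_window * 0.9))
        t += iti
    return trials, pokes


def simulate_learning_curves(n_per_group=None, weeks: int = 4, seed: int = 0,
                             group_effects=None, start: float = 55.0,
                             ceiling: float = 92.0, learn_rate: float = 1.1,
                             animal_sd: float = 3.0, noise_sd: float = 2.5):
    """Weekly percent-correct learning curves for the three cohorts.

    Performance follows a saturating learning curve shared across groups
    (training-week effect) plus per-animal offsets and weekly noise;
    ``group_effects`` (percentage points added per group) default to zero,
    mirroring the finding that discrimination learning does not differ by
    exposure group.  Returns a long DataFrame (animal, group, week,
    percent_correct).
    """
    if n_per_group is None:
        n_per_group = {"SAL": 10, "VPA": 10, "VPA+VNS": 8}
    if group_effects is None:
        group_effects = {g: 0.0 for g in n_per_group}
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in n_per_group.items():
        for a in range(n):
            offset = rng.normal(0.0, animal_sd)
            for w in range(1, weeks + 1):
                mean = ceiling - (ceiling - start) * np.exp(-learn_rate * (w - 1))
                pc = mean + group_effects[g] + offset + rng.normal(0.0, noise_sd)
                rows.append({"animal": f"{g}-b{a:02d}", "group": g,
                             "week": w, "percent_correct": float(np.clip(pc, 0, 100))})
    return pd.DataFrame(rows)
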