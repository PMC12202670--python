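"""Nested mixed-model inference for grouped electrophysiology metrics.

Per-site metrics live in a two-level nesting (recording sites within
animals, animals within exposure groups).  The Gaussian path is a REML
linear mixed model with a random intercept per animal and, when sites
contribute repeated rows, a nested random intercept per site; fixed terms
get block Wald chi-square tests, groups get estimated marginal means (EMMs)
back-transformed to the response scale, and pairwise group contrasts carry
Tukey-adjusted p-values (studentized-range on the animal-level degrees of
freedom).

Non-Gaussian families are documented approximations with the same output
schema: ``tweedie-approx`` fits a Gaussian LMM to ``log(y + c)`` (c = half
the minimum positive value when zeros are present, else 0), ``gaussian-log``
to ``log(y)``, ``beta-approx`` to ``logit(y)``, ``binomial-approx`` to an
empirical logit.  The family actually fitted is recorded in
``FitResult.metadata``; exact Tweedie/beta/binomial mixed-model likelihoods
are out of scope.

Wald tests are computed as block chi-squares on each term's coefficients
from the full fit, which coincides with the marginality-respecting
("Type II") construction for models without interactions and for the
highest-order terms generally; ``FitResult.metadata`` notes this.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "FitResult",
    "shapiro_francia",
    "choose_normality_test",
    "fit_nested_model",
    "emm_backtransform",
]

SUPPORTED_FAMILIES = ("gaussian", "gaussian-log", "tweedie-approx",
                      "beta-approx", "binomial-approx")


# ---------------------------------------------------------------------------
# normality testing
# ---------------------------------------------------------------------------

def shapiro_francia(x):
    """Shapiro-Francia normality test.

    W' is the squared correlation between the order statistics and Blom
    normal scores; the p-value uses Royston's (1993) normal approximation of
    ``log(1 - W')``.  Returns ``(W', p)``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 5:
        raise ValueError("Shapiro-Francia needs n >= 5")
    m = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    w = np.corrcoef(x, m)[0, 1] ** 2
    u, v = math.log(n), math.log(math.log(n))
    mu = -1.2725 + 1.0521 * (v - u)
    sigma = 1.0308 - 0.26758 * (v + 2.0 / u)
    z = (math.log(1.0 - w) - mu) / sigma
    return float(w), float(sps.norm.sf(z))


def choose_normality_test(sample):
    """Kurtosis-routed normality test.

    Leptokurtic samples (Pearson kurtosis >= 3, i.e. heavier-tailed than the
    normal) go to Shapiro-Francia, others to Shapiro-Wilk.  Returns
    ``(test_name, statistic, p, kurtosis)``.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 8:
        raise ValueError("need n >= 8 for normality testing")
    kurt = float(sps.kurtosis(x, fisher=False))  # Pearson convention: normal = 3
    if kurt >= 3.0:
        w, p = shapiro_francia(x)
        return "shapiro-francia", w, p, kurt
    w, p = sps.shapiro(x)
    return "shapiro-wilk", float(w), float(p), kurt


# ---------------------------------------------------------------------------
# model spec / results
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative spec of one nested group-comparison model.

    ``fixed`` lists model terms by column name (interactions as "a:b");
    categorical columns are detected from the data.  ``random`` is the
    two-level nesting ``(animal_col, site_col)``.
    """

    response: str
    fixed: tuple = ("group",)
    random: tuple = ("animal", "site")
    family: str = "gaussian"

    def __post_init__(self):
        if self.family not in SUPPORTED_FAMILIES:
            raise ValueError(f"unsupported family {self.family!r}; "
                             f"supported: {SUPPORTED_FAMILIES}")
        if len(self.random) != 2:
            raise ValueError("random nesting must be (animal, site)")

    @property
    def link(self) -> str:
        return {"gaussian": "identity", "gaussian-log": "log",
                "tweedie-approx": "log", "beta-approx": "logit",
                "binomial-approx": "logit"}[self.family]


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: pd.Series
    se: pd.Series
    wald_table: pd.DataFrame      # term -> chi2, df, p
    emm_table: pd.DataFrame       # group -> emm (response scale), CI, SE
    contrasts: pd.DataFrame       # pair -> estimate (link scale), z, p_tukey
    converged: bool
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# links
# ---------------------------------------------------------------------------

def _inverse_link(link: str, shift: float = 0.0):
    if link == "identity":
        return lambda eta: eta
    if link == "log":
        return lambda eta: np.exp(eta) - shift
    if link == "logit":
        return lambda eta: 1.0 / (1.0 + np.exp(-eta))
    raise ValueError(f"unsupported link {link!r}")


def emm_backtransform(eta: float, se: float, link: str, z: float = 1.96,
                      shift: float = 0.0):
    """Back-transform a linear-predictor mean and SE to the response scale.

    Returns ``(mean, lower, upper)``; monotone links preserve CI ordering.
    ``shift`` undoes a log(y + c) offset.
    """
    inv = _inverse_link(link, shift)
    lo, hi = inv(eta - z * se), inv(eta + z * se)
    return float(inv(eta)), float(min(lo, hi)), float(max(lo, hi))


def _transform_response(y: np.ndarray, family: str):
    """Apply the family's working transform; returns (y_t, shift)."""
    if family == "gaussian":
        return y, 0.0
    if family == "gaussian-log":
        if np.any(y <= 0):
            raise ValueError("gaussian-log requires strictly positive response")
        return np.log(y), 0.0
    if family == "tweedie-approx":
        if np.any(y < 0):
            raise ValueError("tweedie-approx requires non-negative response")
        pos = y[y > 0]
        c = 0.0 if np.all(y > 0) else (0.5 * pos.min() if len(pos) else 0.5)
        return np.log(y + c), c
    if family in ("beta-approx", "binomial-approx"):
        eps = 1.0 / (2.0 * len(y))
        yc = np.clip(y, eps, 1.0 - eps)
        return np.log(yc / (1.0 - yc)), 0.0
    raise ValueError(family)


# ---------------------------------------------------------------------------
# the nested fit
# ---------------------------------------------------------------------------

def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype)


def _formula_term(term: str, data: pd.DataFrame) -> str:
    parts = [f"C({v})" if _is_categorical(data[v]) else v
             for v in term.split(":")]
    return ":".join(parts)


def fit_nested_model(spec: ModelSpec, data: pd.DataFrame,
                     group_col: str = "group") -> FitResult:
    """REML nested linear mixed model with Wald tests, EMMs and Tukey contrasts.

    Requires at least two groups and two animals per group (a single animal
    makes the nesting singular).  Site-level random intercepts are included
    when sites contribute repeated rows; otherwise the site variance is not
    identifiable and folds into the residual (noted in metadata).
    Non-convergence is flagged on the result, never silently swallowed.
    """
    animal_col, site_col = spec.random
    data = data.reset_index(drop=True).copy()
    groups = sorted(data[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    per_group_animals = data.groupby(group_col)[animal_col].nunique()
    if (per_group_animals < 2).any():
        raise ValueError("singular nesting: need >= 2 animals per group")

    y_t, shift = _transform_response(data[spec.response].to_numpy(dtype=float),
                                     spec.family)
    data["_y"] = y_t

    terms = [_formula_term(t, data) for t in spec.fixed]
    formula = "_y ~ " + " + ".join(terms)
    site_replicated = (data.groupby(site_col).size() > 1).any()
    vc = {"site": f"0 + C({site_col})"} if site_replicated else None
    model = smf.mixedlm(formula, data, groups=data[animal_col],
                        re_formula="1", vc_formula=vc)
    # the default optimizer can stall slightly short of the REML optimum on
    # nested variance surfaces; take the best converged fit of two routes
    candidates = []
    for meth in (None, "nm"):
        try:
            fit = (model.fit(reml=True) if meth is None
                   else model.fit(reml=True, method=meth, maxiter=5000))
            candidates.append(fit)
        except Exception:
            continue
    converged_fits = [f for f in candidates
                      if getattr(f, "converged", False) and np.isfinite(f.llf)]
    if not converged_fits:
        converged_fits = [f for f in candidates if np.isfinite(f.llf)]
    if not converged_fits:
        raise RuntimeError("mixed-model fit failed under all optimizers")
    result = max(converged_fits, key=lambda f: f.llf)
    converged = bool(getattr(result, "converged", False))

    fe_names = list(model.exog_names)
    beta = result.fe_params
    cov = result.cov_params().loc[fe_names, fe_names]

    # block Wald chi-square per fixed term
    design_info = model.data.design_info
    rows = []
    for raw, term in zip(spec.fixed, terms):
        sl = design_info.term_name_slices[term]
        idx = fe_names[sl]
        b = beta[idx].to_numpy()
        c = cov.loc[idx, idx].to_numpy()
        chi2 = float(b @ np.linalg.solve(c, b))
        df = len(idx)
        rows.append({"term": raw, "chi2": chi2, "df": df,
                     "p": float(sps.chi2.sf(chi2, df))})
    wald = pd.DataFrame(rows).set_index("term")

    # estimated marginal means: average design rows over a balanced
    # reference grid of the other categorical fixed variables, numerics at
    # their means
    from patsy import build_design_matrices
    fixed_vars = sorted({v for t in spec.fixed for v in t.split(":")})
    cat_vars = [v for v in fixed_vars if v != group_col
                and _is_categorical(data[v])]
    num_vars = [v for v in fixed_vars if v != group_col
                and not _is_categorical(data[v])]
    grid_levels = [sorted(data[v].unique()) for v in cat_vars]

    def design_row(group):
        combos = list(itertools.product(*grid_levels)) if cat_vars else [()]
        ref = pd.DataFrame([
            {group_col: group,
             **dict(zip(cat_vars, combo)),
             **{v: float(data[v].mean()) for v in num_vars}}
            for combo in combos])
        (mat,) = build_design_matrices([design_info], ref)
        return np.asarray(mat).mean(axis=0)

    emm_rows, x_rows = [], {}
    for g in groups:
        x = design_row(g)
        x_rows[g] = x
        eta = float(x @ beta.to_numpy())
        se = float(np.sqrt(x @ cov.to_numpy() @ x))
        mean, lo, hi = emm_backtransform(eta, se, spec.link, shift=shift)
        emm_rows.append({"group": g, "emm": mean, "lower": lo, "upper": hi,
                         "se_link": se, "eta": eta})
    emm = pd.DataFrame(emm_rows).set_index("group")

    # Tukey-adjusted pairwise contrasts on the link scale; the studentized
    # range uses animal-level degrees of freedom
    n_animals = data[animal_col].nunique()
    df_tukey = max(n_animals - len(groups), 2)
    k = len(groups)
    con_rows = []
    for a, b in itertools.combinations(groups, 2):
        l = x_rows[a] - x_rows[b]
        est = float(l @ beta.to_numpy())
        se = float(np.sqrt(l @ cov.to_numpy() @ l))
        z = est / se if se > 0 else 0.0
        p = float(studentized_range.sf(abs(z) * math.sqrt(2.0), k, df_tukey))
        con_rows.append({"contrast": f"{a} - {b}", "estimate": est,
                         "se": se, "z": z, "p_tukey": min(p, 1.0)})
    contrasts = pd.DataFrame(con_rows).set_index("contrast")

    meta = {
        "family_requested": spec.family,
        "family_fitted": ("gaussian LMM on transformed response"
                          if spec.family != "gaussian" else "gaussian LMM"),
        "link": spec.link,
        "log_shift_c": shift,
        "site_random_intercept": bool(site_replicated),
        "wald_type": ("block Wald chi-square per term (Type II for "
                      "interaction-free models)"),
        "n_obs": int(len(data)),
        "n_animals": int(n_animals),
        "reml": True,
        "aic": float(result.aic) if result.aic is not None else float("nan"),
        "bic": float(result.bic) if result.bic is not None else float("nan"),
    }
    return FitResult(spec=spec, coefficients=beta, se=result.bse_fe,
                     wald_table=wald, emm_table=emm, contrasts=contrasts,
                     converged=converged, metadata=meta)
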