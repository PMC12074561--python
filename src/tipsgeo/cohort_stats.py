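"""Cohort-level statistics for stent-geometry risk modelling.

The analysis stage mirrors a standard interventional-radiology workflow:
nonparametric group comparisons between subjects with and without shunt
dysfunction (chi-square for categorical, Mann-Whitney U for continuous
variables), univariate Cox proportional-hazards models per candidate
predictor, forward stepwise multivariate Cox selection (enter while
p < 0.1, remove when p > 0.1), and a sensitivity model that adds the time
from the procedure to CT acquisition.  Proportional-hazards fitting is
delegated to lifelines (Efron tie handling, Wald confidence intervals on
the log-hazard scale); missing values are handled per-analysis
complete-case.

A cohort simulator generates synthetic subject tables whose geometry
covariates match the published cohort's medians and interquartile ranges
and whose event times follow a log-linear exponential hazard, so that the
whole pipeline can be exercised and calibrated without patient data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConvergenceError, NoEventsError, ParameterError

__all__ = [
    "StatsConfig",
    "CoxResult",
    "compare_groups",
    "cox_univariate",
    "cox_forward_stepwise",
    "simulate_cohort",
    "sensitivity_time_to_ct",
    "DEFAULT_EFFECTS",
    "results_to_frame",
]

DURATION_COL = "time_to_event_days"
EVENT_COL = "event"

# hazard ratios used as simulation ground truth: 1.020 per degree of stent
# curvature and 1.061 per mm of cranial-end-to-IVC distance
DEFAULT_EFFECTS = {
    "stent_curvature_deg": float(np.log(1.020)),
    "cranial_tips_stent_end_mm": float(np.log(1.061)),
}


@dataclass(frozen=True)
class StatsConfig:
    """Selection thresholds of the stepwise Cox procedure.

    enter_p / remove_p: a candidate enters while its entry-test p-value is
    below ``enter_p``; an included variable is dropped when its Wald
    p-value exceeds ``remove_p``.  ``entry_test`` chooses the entry
    statistic: "lr" (likelihood ratio against the current model, default)
    or "wald" (the candidate's own Wald test in the augmented model).
    """

    enter_p: float = 0.1
    remove_p: float = 0.1
    significance_p: float = 0.05
    entry_test: str = "lr"

    def __post_init__(self) -> None:
        for p in (self.enter_p, self.remove_p, self.significance_p):
            if not (0.0 < p < 1.0):
                raise ParameterError("p thresholds must lie in (0, 1)")
        if self.entry_test not in ("lr", "wald"):
            raise ParameterError("entry_test must be 'lr' or 'wald'")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "StatsConfig":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class CoxResult:
    """One fitted hazard ratio with its Wald 95% CI and p-value."""

    variable: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def results_to_frame(results: list[CoxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.variable, r.hr, r.ci_low, r.ci_high, r.p, r.n) for r in results],
        columns=["variable", "HR", "ci_low", "ci_high", "p", "n"],
    )


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def compare_groups(
    records: pd.DataFrame,
    group_flag: str,
    variables: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variable two-group comparison table.

    Continuous variables: median (IQR) per group and a two-sided
    Mann-Whitney U p-value.  Categorical variables (declared in
    ``categorical`` or of non-numeric dtype): counts per group and a
    chi-square p-value.  Missing values are excluded pairwise; a variable
    constant across both groups is reported with p = 1 and flagged.
    """
    if group_flag not in records.columns:
        raise ParameterError(f"no group column {group_flag!r}")
    g = records[group_flag].astype(bool)
    if g.all() or (~g).all():
        raise ParameterError("both groups must be non-empty")
    if variables is None:
        variables = [c for c in records.columns if c != group_flag]
    categorical = set(categorical or [])
    rows = []
    for var in variables:
        col = records[var]
        keep = col.notna()
        a = col[keep & ~g]
        b = col[keep & g]
        is_cat = var in categorical or not pd.api.types.is_numeric_dtype(col)
        flag = ""
        if len(a) == 0 or len(b) == 0:
            rows.append((var, "categorical" if is_cat else "continuous",
                         "", "", np.nan, "all-missing"))
            continue
        if col[keep].nunique() <= 1:
            summ = (lambda x: f"{x.iloc[0]} (constant)")
            rows.append((var, "categorical" if is_cat else "continuous",
                         summ(a), summ(b), 1.0, "constant"))
            continue
        if is_cat:
            tab = pd.crosstab(col[keep], g[keep])
            _, p, _, _ = sps.chi2_contingency(tab.to_numpy(), correction=False)
            fmt = lambda x: "/".join(f"{v}" for v in x.value_counts().sort_index())
            rows.append((var, "categorical", fmt(a), fmt(b), float(p), flag))
        else:
            stat_p = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
            fmt = lambda x: (
                f"{x.median():.2f} ({x.quantile(0.25):.2f}-{x.quantile(0.75):.2f})"
            )
            rows.append((var, "continuous", fmt(a), fmt(b), float(stat_p), flag))
    return pd.DataFrame(
        rows, columns=["variable", "type", "group0", "group1", "p", "note"]
    )


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------

def _fit_cox(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str,
    event_col: str,
):
    """Complete-case lifelines CoxPHFitter fit; raises package errors."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError as LLConvergence

    data = df[covariates + [duration_col, event_col]].dropna()
    n_events = int(data[event_col].sum())
    if n_events < 2:
        raise NoEventsError(f"only {n_events} events after complete-case filtering")
    for c in covariates:
        if data[c].nunique() <= 1:
            raise ConvergenceError(f"covariate {c!r} has no variation")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except (LLConvergence, np.linalg.LinAlgError, ValueError) as exc:
        raise ConvergenceError(str(exc)) from exc
    return cph, len(data)


def _results_from_fit(cph, n: int) -> list[CoxResult]:
    s = cph.summary
    return [
        CoxResult(
            variable=str(idx),
            hr=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
            n=n,
        )
        for idx, row in s.iterrows()
    ]


def cox_univariate(
    records: pd.DataFrame,
    variable: str,
    duration_col: str = DURATION_COL,
    event_col: str = EVENT_COL,
) -> CoxResult:
    """Single-covariate proportional-hazards fit (HR per unit of the variable)."""
    cph, n = _fit_cox(records, [variable], duration_col, event_col)
    return _results_from_fit(cph, n)[0]


def cox_forward_stepwise(
    records: pd.DataFrame,
    candidates: list[str],
    duration_col: str = DURATION_COL,
    event_col: str = EVENT_COL,
    cfg: StatsConfig = StatsConfig(),
) -> list[CoxResult]:
    """Forward stepwise Cox selection over ``candidates``.

    Repeatedly adds the candidate with the smallest entry-test p-value
    below ``cfg.enter_p`` and then removes any included variable whose
    Wald p-value exceeds ``cfg.remove_p``, until the model is stable.
    Complete cases over all candidates are used throughout so every
    candidate model sees the same subjects.  An empty final model returns
    an empty list.
    """
    data = records[candidates + [duration_col, event_col]].dropna()
    included: list[str] = []
    current_ll: float | None = None  # partial LL of the current model
    seen: set[frozenset] = set()
    while True:
        changed = False
        best_p, best_var, best_ll = np.inf, None, None
        for cand in candidates:
            if cand in included:
                continue
            try:
                cph, _ = _fit_cox(data, included + [cand], duration_col, event_col)
            except (ConvergenceError, NoEventsError):
                continue
            ll = float(cph.log_likelihood_)
            if cfg.entry_test == "lr":
                if current_ll is None:
                    # null partial log-likelihood recovered from the fit's
                    # own likelihood-ratio test against the null model
                    lr0 = cph.log_likelihood_ratio_test()
                    ref = ll - float(lr0.test_statistic) / 2.0
                else:
                    ref = current_ll
                stat = max(0.0, 2.0 * (ll - ref))
                p = float(sps.chi2.sf(stat, df=1))
            else:
                p = float(cph.summary.loc[cand, "p"])
            if p < best_p:
                best_p, best_var, best_ll = p, cand, ll
        if best_var is not None and best_p < cfg.enter_p:
            included.append(best_var)
            current_ll = best_ll
            changed = True
        # backward removal by Wald p
        while included:
            cph, _ = _fit_cox(data, included, duration_col, event_col)
            current_ll = float(cph.log_likelihood_)
            worst = str(cph.summary["p"].idxmax())
            if float(cph.summary.loc[worst, "p"]) > cfg.remove_p:
                included.remove(worst)
                changed = True
            else:
                break
        if not included:
            current_ll = None
        key = frozenset(included)
        if not changed or key in seen:
            break
        seen.add(key)
    if not included:
        return []
    cph, n = _fit_cox(data, included, duration_col, event_col)
    return _results_from_fit(cph, n)


def sensitivity_time_to_ct(
    records: pd.DataFrame,
    cfg: StatsConfig = StatsConfig(),
    base_variables: tuple = ("stent_curvature_deg", "cranial_tips_stent_end_mm"),
    time_to_ct_col: str = "time_tips_to_ct_days",
    duration_col: str = DURATION_COL,
    event_col: str = EVENT_COL,
) -> list[CoxResult]:
    """Stepwise model including the procedure-to-CT delay as a candidate.

    Records lacking the delay are excluded (complete-case); the number of
    subjects actually used is reported in each result's ``n``.
    """
    if len(records) == 0:
        raise ParameterError("empty cohort")
    candidates = list(base_variables) + [time_to_ct_col]
    missing = [c for c in candidates if c not in records.columns]
    if missing:
        raise ParameterError(f"missing columns: {missing}")
    return cox_forward_stepwise(records, candidates, duration_col, event_col, cfg)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

# (median, iqr_low, iqr_high) of the geometry and covariate distributions
# the simulator emulates
_COHORT_QUANTILES = {
    "cranial_tips_stent_end_mm": (9.99, 2.00, 17.93),
    "minimal_stent_diameter_mm": (8.27, 7.71, 9.01),
    "length_of_covered_stent_portion_mm": (63.03, 55.01, 72.00),
    "stent_curvature_deg": (42.12, 36.47, 50.37),
    "angle_between_covered_stent_ends_deg": (81.60, 66.88, 98.73),
    "alpha_angle_deg": (53.71, 40.64, 64.92),
    "confluence_to_tips_stent_mm": (60.02, 48.02, 77.04),
    "meld": (10.0, 8.0, 13.0),
    "child_pugh_score": (9.0, 7.0, 10.0),
    "pspg_after_mmhg": (8.0, 6.0, 10.75),
}

_Z_IQR = 2.0 * sps.norm.ppf(0.75)  # IQR width in SD units ~ 1.349


def simulate_cohort(
    n: int,
    effects: dict | None = None,
    baseline_rate: float = 0.002,
    censor_rate: float = 0.001,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic subject table with a log-linear exponential hazard.

    Geometry covariates are drawn to match the emulated cohort's medians
    and IQRs: the curvature is lognormal, the cranial-end distance
    exponential (strongly right-skewed, non-negative), the remaining
    continuous covariates normal, clipped to their physical ranges.  Event
    times are exponential with hazard
    ``baseline_rate * exp(sum(beta * (x - median)))`` per day (covariates
    centered at their medians so the baseline refers to a median subject),
    censored by an independent exponential with ``censor_rate``.  The
    default rates yield roughly 30% censoring under the default effects.
    """
    if n < 10:
        raise ParameterError("n must be >= 10")
    if baseline_rate <= 0 or censor_rate < 0:
        raise ParameterError("rates must be positive (censor_rate >= 0)")
    if effects is None:
        effects = dict(DEFAULT_EFFECTS)
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"subject_id": [f"S{i:04d}" for i in range(n)]})

    for col, (med, q1, q3) in _COHORT_QUANTILES.items():
        if col == "stent_curvature_deg":
            sigma = np.log(q3 / q1) / _Z_IQR
            df[col] = rng.lognormal(np.log(med), sigma, n)
        elif col == "cranial_tips_stent_end_mm":
            df[col] = rng.exponential(med / np.log(2.0), n)
        else:
            sd = (q3 - q1) / _Z_IQR
            lo = 0.0
            hi = 180.0 if col.endswith("deg") else np.inf
            df[col] = np.clip(rng.normal(med, sd, n), lo, hi)

    df["nominal_stent_length_cm"] = rng.choice(
        [6.0, 7.0, 8.0, 10.0], n, p=[0.30, 0.25, 0.40, 0.05]
    )
    df["nominal_stent_diameter_mm"] = 10.0
    df["dilatation_mm"] = rng.choice([8.0, 10.0], n, p=[0.85, 0.15])
    df["underdilated"] = (df["dilatation_mm"] < df["nominal_stent_diameter_mm"]).astype(int)
    df["stent_type"] = rng.choice(["VTS", "VCX"], n, p=[0.57, 0.43])
    df["time_tips_to_ct_days"] = rng.exponential(337.0 / np.log(2.0), n)

    lp = np.zeros(n)
    for var, beta in effects.items():
        if var not in df.columns:
            raise ParameterError(f"unknown effect variable {var!r}")
        center = _COHORT_QUANTILES.get(var, (float(df[var].median()),) * 3)[0]
        lp += beta * (df[var].to_numpy() - center)
    hazard = baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0 and np.isfinite(censor_rate):
        t_cens = rng.exponential(1.0 / censor_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    if np.isinf(censor_rate):
        t_cens = np.zeros(n)  # censor everything immediately after baseline
    df[DURATION_COL] = np.minimum(t_event, t_cens)
    df[EVENT_COL] = (t_event <= t_cens).astype(int)
    return df
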