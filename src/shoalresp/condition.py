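"""Body condition, allometric mass correction, and treatment comparisons.

Fulton's condition factor K = 100 * M / L^3 (M wet mass in g, L standard
length in cm) tracks energetic status over the holding period.  Metabolic
rates are mass-corrected by regressing log rate on log mass across the
cohort and carrying each fish's residual to the fitted value at a common
reference mass.  Treatment contrasts come through two routes: a bespoke
paired sign-flip permutation test (exact for small cohorts) and a linear
mixed model with a per-individual random intercept, delegated to
statsmodels, mirroring the conventional repeated-measures analysis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError


def fultons_k(mass_g, length_cm):
    """Fulton's condition factor K = 100 * M / L^3.  Vectorised."""
    m = np.asarray(mass_g, dtype=float)
    length = np.asarray(length_cm, dtype=float)
    if np.any(m <= 0) or np.any(length <= 0):
        raise ValueError("mass and length must be strictly positive")
    k = 100.0 * m / length**3
    return float(k) if k.ndim == 0 else k


def mass_correct(values, masses_g, reference_mass_g: float = 1.84):
    """Carry each fish's metric to a common mass along the cohort allometry.

    Fits OLS of log(value) on log(mass) pooled across the cohort and
    returns ``exp(fitted(log reference mass) + residual_i)`` in input
    order.  With zero mass variance the regression is undefined and the
    input is returned unchanged with a warning.
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(masses_g, dtype=float)
    if v.size != m.size:
        raise ValueError("values and masses differ in length")
    if v.size < 3:
        raise InsufficientDataError("mass correction needs >= 3 fish")
    if np.any(v <= 0) or np.any(m <= 0):
        raise ValueError("values and masses must be strictly positive")
    logm, logv = np.log(m), np.log(v)
    if np.ptp(logm) == 0:
        warnings.warn("zero mass variance; mass correction is a no-op",
                      stacklevel=2)
        return v.copy()
    slope, intercept = np.polyfit(logm, logv, 1)
    resid = logv - (intercept + slope * logm)
    fitted_ref = intercept + slope * np.log(reference_mass_g)
    return np.exp(fitted_ref + resid)


@dataclass(frozen=True)
class TrajectoryResult:
    """Per-treatment condition-factor trajectory over the holding weeks."""

    by_week: pd.DataFrame       # holding, week, mean_k, sem_k, n
    deltas: pd.DataFrame        # fish_id, holding, week_from, week_to, delta_k
    missing_weeks: tuple[int, ...] = ()

    @property
    def complete(self) -> bool:
        return not self.missing_weeks


def condition_trajectory(fish_df: pd.DataFrame) -> TrajectoryResult:
    """Weekly Fulton's K means (+- s.e.m.) per holding treatment.

    ``fish_df`` is the long-format morphometric table (fish_id, holding,
    week, mass_g, length_cm).  Also returns per-fish week-to-week K
    deltas.  Missing weeks yield a partial result flagged through
    ``missing_weeks``; a single fish gives an undefined (NaN) s.e.m.
    """
    df = fish_df.copy()
    df["k"] = fultons_k(df["mass_g"], df["length_cm"])
    present = set(df["week"].unique())
    missing = tuple(sorted({0, 1} - present))
    if missing:
        warnings.warn(f"weeks {missing} absent; trajectory is partial",
                      stacklevel=2)
    by_week = (df.groupby(["holding", "week"])["k"]
                 .agg(mean_k="mean",
                      sem_k=lambda x: (np.std(x, ddof=1) / np.sqrt(len(x))
                                       if len(x) > 1 else np.nan),
                      n="size")
                 .reset_index())
    rows = []
    for fid, grp in df.sort_values("week").groupby("fish_id", sort=False):
        weeks = grp["week"].to_numpy()
        ks = grp["k"].to_numpy()
        for a, b, ka, kb in zip(weeks[:-1], weeks[1:], ks[:-1], ks[1:]):
            rows.append({"fish_id": fid, "holding": grp["holding"].iloc[0],
                         "week_from": int(a), "week_to": int(b),
                         "delta_k": kb - ka})
    deltas = pd.DataFrame(rows, columns=["fish_id", "holding", "week_from",
                                         "week_to", "delta_k"])
    return TrajectoryResult(by_week=by_week, deltas=deltas,
                            missing_weeks=missing)


@dataclass(frozen=True)
class ComparisonResult:
    """Paired two-treatment contrast for one metric."""

    metric: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    mean_percent_reduction: float   # 100*(a-b)/a per fish, then averaged
    p_value: float
    n: int
    exact: bool
    seed: int | None
    n_perm: int | None


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def paired_permutation_test(values_a, values_b, metric: str = "metric",
                            n_perm: int = 10000, seed: int = 0,
                            exact_max_n: int = 12) -> ComparisonResult:
    """Two-sided sign-flip permutation test on paired differences of the mean.

    The null distribution flips the sign of each pair's difference: all
    2^n assignments are enumerated when n <= ``exact_max_n``, otherwise
    ``n_perm`` seeded Monte-Carlo draws are used (with the add-one
    correction so p stays in (0, 1]).  Also reports the mean per-pair
    percent reduction 100*(a-b)/a.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired series differ in length")
    n = a.size
    if n < 2:
        raise InsufficientDataError("paired test needs n >= 2")
    d = a - b
    obs = abs(d.mean())
    eps = 1e-12 * max(1.0, obs)
    if np.all(d == 0):
        p, exact = 1.0, True
        n_perm_used = None
    elif n <= exact_max_n:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        stats_null = np.abs(signs @ d) / n
        p = float(np.mean(stats_null >= obs - eps))
        exact, n_perm_used = True, None
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        stats_null = np.abs(signs @ d) / n
        p = float((1 + np.sum(stats_null >= obs - eps)) / (1 + n_perm))
        exact, n_perm_used = False, n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        reduction = float(np.mean(100.0 * (a - b) / a))
    return ComparisonResult(metric=metric, mean_a=float(a.mean()),
                            mean_b=float(b.mean()), sem_a=_sem(a), sem_b=_sem(b),
                            mean_percent_reduction=reduction, p_value=p,
                            n=n, exact=exact,
                            seed=None if exact else seed, n_perm=n_perm_used)


@dataclass
class MixedModelResult:
    """Fixed-effect estimates from the delegated linear mixed model.

    This is the conventional (non-bespoke) inference path: response ~
    holding + testing + mass with a per-individual random intercept,
    fitted by statsmodels MixedLM.  ``fixed_effects_only`` flags the OLS
    fallback used when the random-effect fit is singular or fails.
    """

    params: dict = field(default_factory=dict)
    wald_stats: dict = field(default_factory=dict)   # z^2, F-type with 1 df
    p_values: dict = field(default_factory=dict)
    converged: bool = False
    fixed_effects_only: bool = False


def mixed_model_compare(df: pd.DataFrame, response: str,
                        fixed: tuple[str, ...] = ("holding", "testing"),
                        covariate: str | None = "mass_g",
                        group: str = "fish_id") -> MixedModelResult:
    """Repeated-measures treatment comparison via a linear mixed model.

    ``df`` needs one row per observation with the response, the fixed
    factors, the mass covariate and the grouping (individual) column;
    each individual should appear at least twice.  Falls back to plain
    OLS (flagged) when the random-intercept fit is singular — e.g. a
    constant response.
    """
    import statsmodels.formula.api as smf

    counts = df.groupby(group).size()
    if (counts < 2).any():
        raise InsufficientDataError("every individual needs >= 2 observations")
    terms = [f"C({f})" for f in fixed]
    if covariate:
        terms.append(covariate)
    formula = f"{response} ~ " + " + ".join(terms)
    resp = df[response].to_numpy(dtype=float)
    if np.ptp(resp) == 0:
        # constant response: mixed fit is degenerate; effects are exactly 0
        res = smf.ols(formula, data=df).fit()
        return _pack_fit(res, converged=True, fixed_only=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed = smf.mixedlm(formula, data=df, groups=df[group]).fit(reml=True)
        if np.any(~np.isfinite(mixed.bse.iloc[:-1])):
            raise ValueError("non-finite standard errors")
        return _pack_fit(mixed, converged=bool(mixed.converged), fixed_only=False)
    except Exception:
        warnings.warn("singular or failed mixed-model fit; falling back to "
                      "fixed-effects-only OLS", stacklevel=2)
        res = smf.ols(formula, data=df).fit()
        return _pack_fit(res, converged=True, fixed_only=True)


def _pack_fit(res, converged: bool, fixed_only: bool) -> MixedModelResult:
    params, wald, pvals = {}, {}, {}
    for name in res.params.index:
        if name in ("Intercept",) or name.startswith("Group"):
            continue
        est = float(res.params[name])
        se = float(res.bse[name])
        params[name] = est
        wald[name] = (est / se) ** 2 if se > 0 else float("inf") if est else 0.0
        pvals[name] = float(res.pvalues[name])
    return MixedModelResult(params=params, wald_stats=wald, p_values=pvals,
                            converged=converged, fixed_effects_only=fixed_only)
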