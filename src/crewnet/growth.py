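"""Longitudinal change over the four waves.

Complete-case repeated-measures ANOVA, paired t tests, linear growth models on
all available observations, person-level Monte-Carlo bootstrap intervals, and
the sensitivity re-analysis that drops a flagged participant.

The growth model is the two-level linear model

    score_pt = (b0 + u0_p) + (b1 + u1_p) * time_t + e_pt

with random person intercepts and slopes, fitted by maximum likelihood; the
reported quantity is the fixed slope ``b1`` (score units per wave by default).
For balanced complete panels this fixed slope equals the mean of the
per-person OLS slopes exactly (the random-effect design matches the fixed
design, so GLS collapses to OLS), and inference uses the exact between-person
t distribution on ``n_persons - 1`` degrees of freedom; unbalanced panels go
through ``statsmodels`` MixedLM with the same t reference, which avoids the
anti-conservative normal-reference Wald p at crew-sized samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import WAVES

logger = logging.getLogger(__name__)

TIME_CODINGS = {
    "wave_index": dict(zip(WAVES, (0.0, 1.0, 2.0, 3.0))),
    "month": dict(zip(WAVES, (0.0, 2.0, 5.0, 8.0))),
}


@dataclass
class RmAnovaResult:
    outcome: str
    F: float
    df_num: int
    df_den: int
    p: float
    n_complete: int


@dataclass
class GrowthFit:
    outcome: str
    slope_estimate: float
    intercept: float
    slope_se: float
    slope_p: float
    n_persons: int
    n_observations: int
    time_coding: str
    engine: str
    converged: bool = True
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)


def outcome_wide(panel: pd.DataFrame, outcome: str, waves=WAVES) -> pd.DataFrame:
    """Person × wave score matrix for one outcome."""
    sub = panel[panel["outcome"] == outcome]
    if sub.empty:
        raise ValueError(f"outcome {outcome!r} absent from panel")
    wide = sub.pivot_table(index="person_id", columns="wave", values="score", dropna=False)
    return wide.reindex(columns=[w for w in waves if w in wide.columns])


def rm_anova(panel: pd.DataFrame, outcome: str, waves=WAVES) -> RmAnovaResult:
    """One-way within-subject ANOVA, complete cases, uncorrected sphericity.

    ``F = MS_time / MS_(time x subject)`` with ``df = (k-1, (k-1)(n-1))``.
    Persons missing any wave are dropped first (listwise deletion).
    """
    wide = outcome_wide(panel, outcome, waves)
    complete = wide.dropna()
    n, k = complete.shape
    if n < 3:
        raise ValueError(f"rm_anova({outcome!r}): needs >= 3 complete cases, found {n}")

    X = complete.to_numpy(dtype=float)
    grand = X.mean()
    ss_time = n * ((X.mean(axis=0) - grand) ** 2).sum()
    resid = X - X.mean(axis=1, keepdims=True) - X.mean(axis=0, keepdims=True) + grand
    ss_err = (resid**2).sum()
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    if ss_err <= 1e-12 * max(ss_time, 1.0):
        # degenerate: no subject-by-time variability left
        F = 0.0 if ss_time <= 1e-12 else np.inf
        p = 1.0 if F == 0.0 else 0.0
        return RmAnovaResult(outcome, F, df_num, df_den, p, n)

    import pingouin as pg  # deferred: slow import

    long = complete.reset_index().melt(
        id_vars="person_id", var_name="wave", value_name="score"
    )
    table = pg.rm_anova(
        data=long, dv="score", within="wave", subject="person_id", correction=False
    )
    row = table.iloc[0]
    return RmAnovaResult(
        outcome=outcome,
        F=float(row["F"]),
        df_num=int(row["ddof1"]),
        df_den=int(row["ddof2"]),
        p=float(row["p_unc"]),
        n_complete=n,
    )


def paired_t(
    panel: pd.DataFrame,
    outcome: str,
    wave_a: str,
    wave_b: str,
    tail: str = "two",
) -> tuple[float, int, float]:
    """Paired t test on within-person differences ``wave_a - wave_b``.

    ``tail="one"`` halves the two-sided p in the direction of the observed
    difference (the directional variant reported alongside the default).
    """
    if tail not in {"two", "one"}:
        raise ValueError("tail must be 'two' or 'one'")
    wide = outcome_wide(panel, outcome)
    pairs = wide[[wave_a, wave_b]].dropna()
    if len(pairs) < 2:
        raise ValueError(f"paired_t({outcome!r}): needs >= 2 persons at both waves")
    diff = pairs[wave_a] - pairs[wave_b]
    df = len(diff) - 1
    if diff.std(ddof=1) == 0:
        if diff.mean() == 0:
            return 0.0, df, 1.0
        logger.warning("paired_t(%s): zero variance of nonzero differences", outcome)
        return float(np.sign(diff.mean()) * np.inf), df, 0.0
    res = stats.ttest_rel(pairs[wave_a], pairs[wave_b])
    t, p = float(res.statistic), float(res.pvalue)
    if tail == "one":
        p = p / 2.0
    return t, df, p


def _long_scores(panel: pd.DataFrame, outcome: str, time_coding: str) -> pd.DataFrame:
    codes = TIME_CODINGS[time_coding]
    sub = panel[(panel["outcome"] == outcome) & panel["score"].notna()].copy()
    sub = sub[sub["wave"].isin(list(codes))]
    sub["time"] = sub["wave"].map(codes)
    return sub[["person_id", "time", "score"]].reset_index(drop=True)


def _person_lines(long: pd.DataFrame) -> pd.DataFrame:
    """Per-person OLS slope and intercept (persons with >= 2 waves)."""
    rows = []
    for person, sub in long.groupby("person_id"):
        if len(sub) < 2 or sub["time"].nunique() < 2:
            continue
        t = sub["time"].to_numpy(dtype=float)
        y = sub["score"].to_numpy(dtype=float)
        tc = t - t.mean()
        slope = float((tc * (y - y.mean())).sum() / (tc**2).sum())
        rows.append((person, slope, float(y.mean() - slope * t.mean())))
    return pd.DataFrame(rows, columns=["person_id", "slope", "intercept"])


def _is_balanced(long: pd.DataFrame) -> bool:
    counts = long.groupby("person_id")["time"].agg(["size", "nunique"])
    n_times = long["time"].nunique()
    return bool((counts["size"] == n_times).all() and (counts["nunique"] == n_times).all())


def fit_growth(
    panel: pd.DataFrame,
    outcome: str,
    time_coding: str = "wave_index",
    engine: str = "auto",
) -> GrowthFit:
    """Fit the linear growth model and test the fixed slope of time.

    ``engine="balanced"`` uses the exact closed form available for balanced
    complete panels; ``engine="mixedlm"`` always fits the mixed model (ML),
    falling back to a random-intercept-only model when the slope variance is
    degenerate or the full fit does not converge; ``"auto"`` picks the closed
    form exactly when it applies.
    """
    long = _long_scores(panel, outcome, time_coding)
    return _fit_long(long, outcome, time_coding, engine)


def _fit_long(
    long: pd.DataFrame, outcome: str, time_coding: str, engine: str
) -> GrowthFit:
    n_persons = long["person_id"].nunique()
    n_obs = len(long)
    if n_persons < 3:
        raise ValueError(f"fit_growth({outcome!r}): needs >= 3 persons, found {n_persons}")

    balanced = _is_balanced(long)
    if engine == "auto":
        engine = "balanced" if balanced else "mixedlm"
    if engine == "balanced":
        if not balanced:
            raise ValueError("engine='balanced' requires a balanced complete panel")
        lines = _person_lines(long)
        slopes = lines["slope"].to_numpy()
        n = len(slopes)
        beta1 = float(slopes.mean())
        beta0 = float(lines["intercept"].mean())
        se = float(slopes.std(ddof=1) / np.sqrt(n))
        if se == 0:
            p = 1.0 if beta1 == 0 else 0.0
        else:
            p = float(2 * stats.t.sf(abs(beta1 / se), n - 1))
        return GrowthFit(outcome, beta1, beta0, se, p, n, n_obs, time_coding, "balanced")
    if engine != "mixedlm":
        raise ValueError(f"unknown engine {engine!r}")

    import statsmodels.formula.api as smf

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("score ~ time", long, groups=long["person_id"], re_formula="~time")
        try:
            fit = model.fit(reml=False)
            slope_var = float(fit.cov_re.iloc[1, 1])
            degenerate = not fit.converged or not np.isfinite(fit.bse["time"]) or slope_var < 1e-8
        except (np.linalg.LinAlgError, ValueError):
            degenerate = True
        if degenerate:
            converged = False
            model = smf.mixedlm("score ~ time", long, groups=long["person_id"])
            fit = model.fit(reml=False)
    beta1 = float(fit.params["time"])
    se = float(fit.bse["time"])
    # t reference with between-person df, not the asymptotic normal
    p = float(2 * stats.t.sf(abs(beta1 / se), max(n_persons - 1, 1))) if se > 0 else 0.0
    return GrowthFit(
        outcome, beta1, float(fit.params["Intercept"]), se, p,
        n_persons, n_obs, time_coding, "mixedlm", converged,
    )


def bootstrap_ci(
    panel: pd.DataFrame,
    outcome: str,
    B: int = 2000,
    seed: int | np.random.Generator | None = None,
    time_coding: str = "wave_index",
    engine: str = "auto",
    level: float = 0.95,
    return_slopes: bool = False,
):
    """Person-level Monte-Carlo bootstrap percentile CI for the growth slope.

    The resampling unit is the person — all of a person's waves move together —
    and each resample refits the same growth procedure; the interval is the
    percentile band of the ``B`` refitted fixed slopes. Reproducible under a
    fixed seed. For balanced panels the refit uses the closed form (identical
    point estimate, vectorized over resamples).
    """
    if B < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    long = _long_scores(panel, outcome, time_coding)
    persons = long["person_id"].unique()
    n = len(persons)
    alpha = (1 - level) / 2

    if _is_balanced(long) and engine in {"auto", "balanced"}:
        slopes = _person_lines(long).set_index("person_id").loc[persons, "slope"].to_numpy()
        idx = rng.integers(0, n, size=(B, n))
        boot = slopes[idx].mean(axis=1)
    else:
        by_person = {p: sub for p, sub in long.groupby("person_id")}
        boot = np.full(B, np.nan)
        failures = 0
        for b in range(B):
            chosen = rng.choice(persons, size=n, replace=True)
            frames = []
            for k, p in enumerate(chosen):
                sub = by_person[p].copy()
                sub["person_id"] = f"bs{k}"
                frames.append(sub)
            resample = pd.concat(frames, ignore_index=True)
            try:
                boot[b] = _fit_long(resample, outcome, time_coding, engine).slope_estimate
            except (ValueError, np.linalg.LinAlgError):
                failures += 1
        if failures > 0.1 * B:
            raise RuntimeError(
                f"bootstrap_ci({outcome!r}): {failures}/{B} refits failed"
            )
        boot = boot[np.isfinite(boot)]
    lo, hi = np.quantile(boot, [alpha, 1 - alpha])
    if return_slopes:
        return float(lo), float(hi), boot
    return float(lo), float(hi)


def sensitivity_exclude(panel: pd.DataFrame, person_id: str) -> pd.DataFrame:
    """Panel minus one person's rows; downstream statistics re-run unchanged."""
    if person_id not in set(panel["person_id"]):
        raise KeyError(f"person {person_id!r} not in panel")
    return panel[panel["person_id"] != person_id].reset_index(drop=True)
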