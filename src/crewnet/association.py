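"""Linking sensor-network metrics to psychological scores.

Every repeated measure x of person p at deployment t is decomposed as

    x_p(t) = xbar_p + delta_p(t)

where ``xbar_p`` is the person's mean over their observed deployments and
``delta_p(t)`` the wave-specific deviation (person-mean centering). Pooled
deviations feed within-person Spearman correlations — does a person report
more conflict in the deployments where they also accumulate more contact time?
— while person means feed across-person correlations, comparing individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: the study's correlation-panel measures, sensor metrics first
DEFAULT_MEASURES = (
    "strength",
    "gini",
    "loneliness",
    "ideas_of_reference",
    "persecutory",
    "cohesion",
    "conflict",
    "performance",
)


@dataclass
class PersonCenteredPanel:
    """Exact decomposition of a person × wave × measure panel."""

    observed: pd.DataFrame  # (person_id, wave) index, measure columns
    means: pd.DataFrame  # person_id index, measure columns
    deviations: pd.DataFrame  # same shape as observed; NaN where excluded

    def reconstruct(self) -> pd.DataFrame:
        persons = self.observed.index.get_level_values("person_id")
        return self.deviations + self.means.reindex(persons).set_index(self.observed.index)


@dataclass
class CorrelationMatrix:
    scope: str  # "within_person" | "across_person"
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame


def merge_panel(
    score_panel: pd.DataFrame, sensor_metrics: pd.DataFrame
) -> pd.DataFrame:
    """Join scored outcomes with per-deployment sensor metrics.

    ``score_panel`` is tidy ``(person_id, wave, outcome, score)``;
    ``sensor_metrics`` is tidy ``(person_id, wave, strength, gini, ...)``.
    Returns a wide frame indexed by ``(person_id, wave)``.
    """
    wide = score_panel.pivot_table(
        index=["person_id", "wave"], columns="outcome", values="score", dropna=False
    )
    sensors = sensor_metrics.set_index(["person_id", "wave"])
    merged = wide.join(sensors, how="outer")
    merged.columns.name = None
    return merged


def person_center(merged: pd.DataFrame, min_waves: int = 2) -> PersonCenteredPanel:
    """Person-mean center every measure.

    Missing waves are excluded from that person's mean; persons observed at
    fewer than ``min_waves`` waves of a measure are excluded from the
    within-person scope for that measure (their deviations are masked).
    """
    persons = merged.index.get_level_values("person_id")
    means = merged.groupby(level="person_id").mean()
    counts = merged.groupby(level="person_id").count()
    deviations = merged - means.reindex(persons).set_index(merged.index)
    too_few = counts < min_waves
    if too_few.to_numpy().any():
        for measure in merged.columns:
            excluded = counts.index[too_few[measure]].tolist()
            if excluded:
                logger.warning(
                    "within-person scope: excluding %s for %r (< %d waves)",
                    excluded, measure, min_waves,
                )
        mask = too_few.reindex(persons).set_index(merged.index)
        deviations = deviations.mask(mask)
    return PersonCenteredPanel(observed=merged, means=means, deviations=deviations)


def _spearman(x: np.ndarray, y: np.ndarray, min_n: int = 5) -> tuple[float, float, int]:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < min_n:
        raise ValueError(f"need >= {min_n} paired observations, found {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("degenerate (constant) vector: Spearman undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), n


def within_person_spearman(
    centered: PersonCenteredPanel, measure_x: str, measure_y: str, min_n: int = 5
) -> tuple[float, float, int]:
    """Spearman rho on pooled person-mean-centered deviations (two-sided p)."""
    d = centered.deviations
    return _spearman(d[measure_x].to_numpy(), d[measure_y].to_numpy(), min_n)


def across_person_spearman(
    centered: PersonCenteredPanel, measure_x: str, measure_y: str, min_n: int = 5
) -> tuple[float, float, int]:
    """Spearman rho on person means (two-sided p)."""
    m = centered.means
    return _spearman(m[measure_x].to_numpy(), m[measure_y].to_numpy(), min_n)


def significance_stars(p: float) -> str:
    """The heatmap's marking scheme, including the marginal band."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "†"
    return ""


def correlation_heatmap_table(
    centered: PersonCenteredPanel,
    measures: tuple[str, ...] = DEFAULT_MEASURES,
    scope: str = "within_person",
    min_n: int = 5,
) -> CorrelationMatrix:
    """Full symmetric Spearman matrix with significance marks.

    Cells whose pairings are degenerate or too sparse are left NaN rather than
    silently dropped.
    """
    if scope == "within_person":
        corr = within_person_spearman
    elif scope == "across_person":
        corr = across_person_spearman
    else:
        raise ValueError("scope must be 'within_person' or 'across_person'")
    measures = tuple(m for m in measures if m in centered.observed.columns)
    k = len(measures)
    rho = pd.DataFrame(np.eye(k), index=measures, columns=measures)
    p = pd.DataFrame(np.nan, index=measures, columns=measures)
    n = pd.DataFrame(0, index=measures, columns=measures, dtype=int)
    for a in range(k):
        for b in range(a + 1, k):
            try:
                r, pv, nn = corr(centered, measures[a], measures[b], min_n)
            except ValueError:
                r, pv, nn = np.nan, np.nan, 0
            rho.iloc[a, b] = rho.iloc[b, a] = r
            p.iloc[a, b] = p.iloc[b, a] = pv
            n.iloc[a, b] = n.iloc[b, a] = nn
    stars = p.map(significance_stars)
    return CorrelationMatrix(scope, rho, p, n, stars)
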