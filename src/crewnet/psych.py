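"""Questionnaire scoring: scale definitions, reliability, severity flags.

Five instruments are scored per person and wave: a 20-item loneliness scale
(options 1–4, summed, range 20–80), the two 16-item paranoid-thoughts
subscales — ideas of reference and persecutory ideation (options 1–5, summed,
range 16–80 each) — a 6-item team-cohesion scale, a 6-item team-conflict scale
split into task and relationship halves, and a 3-item individual-performance
scale (all options 1–5, item means, range 1–5). The six conflict items are
additionally averaged into an overall team-conflict index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import WAVES


@dataclass(frozen=True)
class ScaleDefinition:
    scale_id: str
    n_items: int
    option_range: tuple[int, int]
    aggregation: str  # "sum" | "mean"
    reverse_keyed: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.aggregation not in {"sum", "mean"}:
            raise ValueError("aggregation must be 'sum' or 'mean'")
        bad = [i for i in self.reverse_keyed if not 1 <= i <= self.n_items]
        if bad:
            raise ValueError(f"reverse-keyed indices out of range: {bad}")

    @property
    def score_range(self) -> tuple[float, float]:
        lo, hi = self.option_range
        if self.aggregation == "sum":
            return (lo * self.n_items, hi * self.n_items)
        return (float(lo), float(hi))

    def recode(self, item_index: int, response: float) -> float:
        lo, hi = self.option_range
        return lo + hi - response if item_index in self.reverse_keyed else response


#: conventional reverse-keyed items of the 20-item loneliness instrument
LONELINESS_REVERSE_ITEMS = frozenset({1, 5, 6, 9, 10, 15, 16, 19, 20})


def default_scales(reverse_keys: bool = False) -> dict[str, ScaleDefinition]:
    """The study battery.

    ``reverse_keys=True`` applies the loneliness scale's standard reverse-keyed
    item set; the default assumes responses are already recoded (as deposited
    anonymized data typically are).
    """
    lonely_rev = LONELINESS_REVERSE_ITEMS if reverse_keys else frozenset()
    return {
        "loneliness": ScaleDefinition("loneliness", 20, (1, 4), "sum", lonely_rev),
        "ideas_of_reference": ScaleDefinition("ideas_of_reference", 16, (1, 5), "sum"),
        "persecutory": ScaleDefinition("persecutory", 16, (1, 5), "sum"),
        "cohesion": ScaleDefinition("cohesion", 6, (1, 5), "mean"),
        "conflict_task": ScaleDefinition("conflict_task", 3, (1, 5), "mean"),
        "conflict_relationship": ScaleDefinition("conflict_relationship", 3, (1, 5), "mean"),
        "performance": ScaleDefinition("performance", 3, (1, 5), "mean"),
    }


GPTS_SUBSCALES = ("ideas_of_reference", "persecutory")
#: outcomes reported longitudinally (overall conflict replaces its two halves)
OUTCOMES = (
    "loneliness",
    "ideas_of_reference",
    "persecutory",
    "cohesion",
    "conflict",
    "performance",
)


def score_scale(
    responses: pd.DataFrame,
    definition: ScaleDefinition,
    max_missing_frac: float = 0.0,
) -> float:
    """Score one person/wave/scale from item rows (``item_index``, ``response``).

    Reverse-keyed items are recoded as ``min + max − response``. By default a
    score requires the complete item set; with ``max_missing_frac > 0`` up to
    that fraction of items may be absent and the person's item mean stands in
    for each missing item.
    """
    lo, hi = definition.option_range
    items = responses.set_index("item_index")["response"].astype(float)
    if items.index.duplicated().any():
        raise ValueError(f"{definition.scale_id}: duplicate item indices")
    out_of_range = (items < lo) | (items > hi)
    if out_of_range.any():
        raise ValueError(
            f"{definition.scale_id}: responses outside [{lo}, {hi}]: "
            f"items {sorted(items.index[out_of_range])}"
        )
    recoded = pd.Series(
        {idx: definition.recode(idx, val) for idx, val in items.items()}, dtype=float
    )
    n_missing = definition.n_items - len(recoded)
    if n_missing < 0:
        raise ValueError(f"{definition.scale_id}: more items than defined")
    if n_missing > max_missing_frac * definition.n_items:
        return float("nan")
    if n_missing:
        recoded = pd.concat([recoded, pd.Series([recoded.mean()] * n_missing)])
    score = recoded.sum() if definition.aggregation == "sum" else recoded.mean()
    smin, smax = definition.score_range
    return float(min(max(score, smin), smax))


def overall_conflict(task_score: float, relationship_score: float) -> float:
    """Overall team-conflict index: mean of the six items, i.e. the mean of the
    two 3-item subscale means."""
    if np.isnan(task_score) or np.isnan(relationship_score):
        return float("nan")
    return (task_score + relationship_score) / 2.0


def score_panel(
    responses: pd.DataFrame,
    scales: dict[str, ScaleDefinition] | None = None,
    max_missing_frac: float = 0.0,
) -> pd.DataFrame:
    """Score a long-format response table into a tidy outcome panel.

    Returns rows ``(person_id, wave, outcome, score)`` including the derived
    overall ``conflict`` index. Rows that already carry a ``score`` column
    (scale-level deposits) pass through unscored.
    """
    scales = scales or default_scales()
    records = []
    if "score" in responses.columns and "response" not in responses.columns:
        for r in responses.itertuples():
            records.append((r.person_id, r.wave, r.scale_id, float(r.score)))
    else:
        grouped = responses.groupby(["person_id", "wave", "scale_id"], sort=True)
        for (person, wave, scale_id), sub in grouped:
            if scale_id not in scales:
                raise ValueError(f"unknown scale {scale_id!r}")
            score = score_scale(sub, scales[scale_id], max_missing_frac)
            records.append((person, wave, scale_id, score))
    panel = pd.DataFrame(records, columns=["person_id", "wave", "outcome", "score"])

    halves = panel[panel["outcome"].isin(["conflict_task", "conflict_relationship"])]
    if not halves.empty:
        wide = halves.pivot_table(
            index=["person_id", "wave"], columns="outcome", values="score", dropna=False
        )
        if {"conflict_task", "conflict_relationship"} <= set(wide.columns):
            conflict = [
                (p, w, "conflict", overall_conflict(r["conflict_task"], r["conflict_relationship"]))
                for (p, w), r in wide.iterrows()
            ]
            panel = pd.concat(
                [panel, pd.DataFrame(conflict, columns=panel.columns)], ignore_index=True
            )
    wave_order = {w: k for k, w in enumerate(WAVES)}
    panel = panel.sort_values(
        ["person_id", "wave", "outcome"],
        key=lambda s: s.map(wave_order).fillna(-1) if s.name == "wave" else s,
    ).reset_index(drop=True)
    return panel.dropna(subset=["score"]).reset_index(drop=True)


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha of a persons × items matrix (sample variances).

    ``alpha = k/(k-1) * (1 - sum(item variances) / var(total))``; undefined
    when the total score does not vary.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("alpha needs a 2-D matrix with >= 2 items")
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] < 3:
        raise ValueError("alpha needs >= 3 complete respondents")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: total score has zero variance")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


def flag_severe(score: float, scale_id: str, threshold: float = 40.0) -> bool:
    """Severity flag for paranoid-thoughts subscales: strictly above threshold."""
    if scale_id not in GPTS_SUBSCALES:
        raise ValueError(f"severity flag applies to {GPTS_SUBSCALES}, not {scale_id!r}")
    return bool(score > threshold)


def with_reverse_keys(
    scales: dict[str, ScaleDefinition], scale_id: str, items: frozenset[int]
) -> dict[str, ScaleDefinition]:
    """Return a copy of a scale config with one scale's reverse-key set replaced."""
    out = dict(scales)
    out[scale_id] = replace(out[scale_id], reverse_keyed=items)
    return out
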