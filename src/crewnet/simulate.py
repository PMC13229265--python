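"""Ground-truthed synthetic crew data: contact streams and questionnaires.

The generator emulates a small overwintering crew monitored with wearable
proximity sensors over four two-week deployments. It is deliberately a
*minimal* behavioural model — a fixed daily block schedule (meals in the
cafeteria, work in assigned rooms, evenings in the lounge or near quarters)
with Bernoulli contact emission per 10-s slot — because its job is to induce,
with known ground truth, exactly the structures the analysis measures:

* room-driven gathering (cafeteria and lounge dominate room strength);
* tunable nationality homophily (within-group contact probabilities exceed
  cross-group ones by a per-deployment ratio that rises over the mission);
* a declining overall activity level across deployments (the daily-strength
  distribution shifts down between the first and last deployment);
* nonwear lapses: with probability ``p_nonwear`` a person-day emits no rows at
  all, producing zero-contact days for wearables but not for room sensors;
* two mid-mission crew replacements at the first wave boundary;
* questionnaire panels following a linear growth model with prescribed fixed
  slopes, random person effects, optional within-person coupling to contact
  strength, and item-level expansion hitting a target Cronbach's alpha.

Every simulated dataset is reproducible from its seed and ships with a
``GroundTruth`` record sufficient to compute the expected value of each
pipeline output.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    RESOLUTION,
    SECONDS_PER_DAY,
    WAVES,
    DeploymentWindow,
    canonicalize_contacts,
    validate_roster,
    write_contacts,
    write_responses,
    write_roster,
    write_windows,
)
from .psych import OUTCOMES, ScaleDefinition, default_scales

HOUR = 3600

# -- daily schedule ----------------------------------------------------------


@dataclass(frozen=True)
class Block:
    """One schedule block of the simulated day; times in seconds from midnight."""

    name: str
    start: int
    end: int
    kind: str  # "meal" | "work" | "evening"

    @property
    def n_slots(self) -> int:
        return (self.end - self.start) // RESOLUTION


DEFAULT_BLOCKS = (
    Block("breakfast", int(7.5 * HOUR), int(8.5 * HOUR), "meal"),
    Block("morning_work", 9 * HOUR, 12 * HOUR, "work"),
    Block("lunch", int(12.5 * HOUR), int(13.5 * HOUR), "meal"),
    Block("afternoon_work", 14 * HOUR, 18 * HOUR, "work"),
    Block("dinner", 19 * HOUR, 20 * HOUR, "meal"),
    Block("evening", int(20.5 * HOUR), 23 * HOUR, "evening"),
)

#: two nationality groups plus the out-group medical doctor, 12 active members
DEFAULT_PERSON_GROUPS: Mapping[str, str] = {
    "A": "IT", "B": "IT", "C": "IT", "E": "IT", "G": "IT", "I": "IT",
    "D": "FR", "F": "FR", "H": "FR", "J": "FR", "K": "FR",
    "L": "ESA-MD",
}

DEFAULT_ROOMS = (
    ("cafeteria", "shared"),
    ("lounge", "shared"),
    ("gym", "shared"),
    ("lab", "shared"),
    ("workshop", "shared"),
    ("radio_room", "shared"),
    ("corridor_a", "accommodation"),
    ("corridor_b", "accommodation"),
    ("quarters_hall", "accommodation"),
)


@dataclass
class GrowthParams:
    """Generative parameters of one outcome's growth trajectory."""

    beta0: float
    beta1: float
    sd_intercept: float
    sd_slope: float
    sd_resid: float
    #: target within-person correlation between residuals and strength deviations
    coupling: float = 0.0
    #: additive per-wave deviations from the linear trend (e.g. polar-night peak)
    wave_effects: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)


#: study-condition trajectories; slopes are per wave (0, 1, 2, 3)
DEFAULT_GROWTH_PARAMS: Mapping[str, GrowthParams] = {
    "loneliness": GrowthParams(36.0, 2.42, 7.0, 0.8, 4.5, 0.25),
    "ideas_of_reference": GrowthParams(
        17.5, 1.35, 4.0, 1.0, 5.0, 0.30, (0.0, 0.0, 2.5, 0.0)
    ),
    "persecutory": GrowthParams(18.0, 2.35, 4.0, 1.0, 6.0, 0.30),
    "cohesion": GrowthParams(4.3, -0.42, 0.35, 0.10, 0.50, -0.35),
    "conflict": GrowthParams(1.7, 0.35, 0.30, 0.10, 0.40, 0.40),
    "performance": GrowthParams(4.4, -0.24, 0.30, 0.10, 0.40, -0.30),
}

DEFAULT_ALPHA_TARGETS: Mapping[str, float] = {
    "loneliness": 0.90,
    "ideas_of_reference": 0.90,
    "persecutory": 0.95,
    "cohesion": 0.95,
    "conflict_task": 0.90,
    "conflict_relationship": 0.90,
    "performance": 0.93,
}

INDIVIDUAL_BATTERY = ("loneliness", "ideas_of_reference", "persecutory")
TEAM_BATTERY = ("cohesion", "conflict", "performance")


@dataclass
class CrewScenario:
    """Study conditions for one simulated mission."""

    seed: int = 7
    person_groups: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PERSON_GROUPS)
    )
    #: (departing member, arriving replacement) at the first wave boundary
    replacements: tuple[tuple[str, str], ...] = (("E", "M"), ("H", "N"))
    deployments: tuple[tuple[str, int], ...] = (
        ("M1", 0), ("M3", 60), ("M6", 150), ("M9", 240)
    )
    days_per_deployment: int = 14
    rooms: tuple[tuple[str, str], ...] = DEFAULT_ROOMS
    blocks: tuple[Block, ...] = DEFAULT_BLOCKS
    #: within/cross-group contact-probability ratio, rising over the mission
    homophily_schedule: Mapping[str, float] = field(
        default_factory=lambda: {"M1": 1.2, "M3": 1.5, "M6": 2.0, "M9": 2.5}
    )
    #: overall person-person activity multiplier, declining over the mission
    activity_schedule: Mapping[str, float] = field(
        default_factory=lambda: {"M1": 1.0, "M3": 0.9, "M6": 0.8, "M9": 0.7}
    )
    p_nonwear: float = 0.38
    p_contact: float = 0.03
    work_contact_factor: float = 0.5
    p_room_social: float = 0.25
    p_room_work: float = 0.04
    p_meal_attend: float = 0.92
    p_work_attend: float = 0.95
    p_evening_lounge: float = 0.6
    #: (person, wave, battery) questionnaire omissions; battery in
    #: {"individual", "team", "all"}
    missing_waves: tuple[tuple[str, str, str], ...] = (("K", "M9", "individual"),)
    #: one member reporting severe paranoid ideation (intercept shift > 40)
    severe_paranoia_person: str | None = "I"
    severe_paranoia_shift: float = 28.0

    def __post_init__(self) -> None:
        probs = [
            self.p_nonwear, self.p_contact, self.p_room_social, self.p_room_work,
            self.p_meal_attend, self.p_work_attend, self.p_evening_lounge,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(r <= 0 for r in self.homophily_schedule.values()):
            raise ValueError("homophily ratios must be positive")
        ordered = sorted(self.blocks, key=lambda b: b.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(f"schedule blocks {a.name!r} and {b.name!r} overlap")

    # -- derived structure --------------------------------------------------

    @property
    def wave_labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.deployments)

    @property
    def windows(self) -> list[DeploymentWindow]:
        return [
            DeploymentWindow(label, start, start + self.days_per_deployment)
            for label, start in self.deployments
        ]

    @property
    def mission_end_day(self) -> int:
        return self.windows[-1].end_day

    def all_persons(self) -> dict[str, str]:
        """Person → group, replacements inheriting the departing member's group."""
        groups = dict(self.person_groups)
        for out, new in self.replacements:
            if out not in groups:
                raise ValueError(f"replacement departs unknown member {out!r}")
            groups[new] = groups[out]
        return groups

    def presence(self) -> dict[str, tuple[int, int]]:
        """Inclusive presence day spans per person."""
        first_window = self.windows[0]
        spans = {p: (0, self.mission_end_day - 1) for p in self.person_groups}
        for out, new in self.replacements:
            spans[out] = (0, first_window.end_day - 1)
            spans[new] = (self.windows[1].start_day, self.mission_end_day - 1)
        return spans

    def work_room_of(self) -> dict[str, str]:
        """Deterministic work-room assignment, mixing groups within rooms.

        Persons are interleaved across nationality groups and then chunked
        into consecutive room teams, so work co-location is close to
        group-balanced and does not itself induce homophily.
        """
        work_rooms = [
            name for name, cat in self.rooms
            if cat == "shared" and name not in ("cafeteria", "lounge")
        ]
        groups = self.all_persons()
        by_group: dict[str, list[str]] = {}
        for p in sorted(groups):
            by_group.setdefault(groups[p], []).append(p)
        interleaved = [
            p
            for tier in itertools.zip_longest(*by_group.values())
            for p in tier
            if p is not None
        ]
        size = -(-len(interleaved) // len(work_rooms))  # ceil division
        return {
            p: work_rooms[k // size] for k, p in enumerate(interleaved)
        }

    def home_area_of(self) -> dict[str, str]:
        homes = [name for name, cat in self.rooms if cat == "accommodation"]
        persons = sorted(self.all_persons())
        return {p: homes[k % len(homes)] for k, p in enumerate(persons)}


def make_roster(scenario: CrewScenario) -> pd.DataFrame:
    groups = scenario.all_persons()
    spans = scenario.presence()
    rows = [
        {
            "sensor_id": p, "kind": "person", "group": g, "room_category": None,
            "first_day": spans[p][0], "last_day": spans[p][1],
        }
        for p, g in sorted(groups.items())
    ]
    rows += [
        {
            "sensor_id": name, "kind": "room", "group": None, "room_category": cat,
            "first_day": 0, "last_day": scenario.mission_end_day - 1,
        }
        for name, cat in scenario.rooms
    ]
    return validate_roster(pd.DataFrame(rows))


def _pair_probability(
    scenario: CrewScenario, block: Block, same_group: bool, wave: str
) -> float:
    p = scenario.p_contact * scenario.activity_schedule[wave]
    if same_group:
        p *= scenario.homophily_schedule[wave]
    if block.kind == "work":
        p *= scenario.work_contact_factor
    return min(p, 0.95)


def simulate_contacts(
    scenario: CrewScenario, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate the mission's contact stream and its ground truth.

    Returns a canonical contact frame ``(t, i, j, duration)`` and a truth dict
    holding expected person-pair contact hours per deployment, the nonwear
    person-days actually drawn, and the generating schedule parameters.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    groups = scenario.all_persons()
    spans = scenario.presence()
    work_room = scenario.work_room_of()
    home_area = scenario.home_area_of()

    ts, is_, js = [], [], []
    nonwear_days: list[tuple[str, int]] = []

    def emit(day: int, block: Block, a: str, b: str, n_slots: int) -> None:
        slots = rng.choice(block.n_slots, size=n_slots, replace=False)
        t0 = day * SECONDS_PER_DAY + block.start
        ts.append(t0 + slots.astype(np.int64) * RESOLUTION)
        is_.extend([a] * n_slots)
        js.extend([b] * n_slots)

    for window in scenario.windows:
        wave = window.label
        present = [
            p for p in sorted(groups)
            if spans[p][0] <= window.start_day and spans[p][1] >= window.end_day - 1
        ]
        # evening lounge attendance declines with the activity schedule
        # (social withdrawal); meals stay mandatory-ish throughout
        p_lounge = scenario.p_evening_lounge * scenario.activity_schedule[wave]
        for day in window.days:
            worn = {p: bool(rng.random() >= scenario.p_nonwear) for p in present}
            nonwear_days.extend((p, day) for p in present if not worn[p])
            lounge_tonight = {p: bool(rng.random() < p_lounge) for p in present}
            for block in scenario.blocks:
                # room occupancy for this block
                occupancy: dict[str, list[str]] = {}
                for p in present:
                    if block.kind == "meal":
                        if rng.random() >= scenario.p_meal_attend:
                            continue
                        room = "cafeteria"
                    elif block.kind == "work":
                        if rng.random() >= scenario.p_work_attend:
                            continue
                        room = work_room[p]
                    else:  # evening
                        room = "lounge" if lounge_tonight[p] else home_area[p]
                    occupancy.setdefault(room, []).append(p)

                p_room = (
                    scenario.p_room_work if block.kind == "work"
                    else scenario.p_room_social
                )
                for room, occupants in occupancy.items():
                    social = not any(
                        name == room and cat == "accommodation"
                        for name, cat in scenario.rooms
                    )
                    worn_occ = [p for p in occupants if worn[p]]
                    if social:
                        for a, b in itertools.combinations(worn_occ, 2):
                            p_pair = _pair_probability(
                                scenario, block, groups[a] == groups[b], wave
                            )
                            n = rng.binomial(block.n_slots, p_pair)
                            if n:
                                emit(day, block, a, b, n)
                    for p in worn_occ:
                        n = rng.binomial(block.n_slots, p_room)
                        if n:
                            emit(day, block, p, room, n)

    if ts:
        contacts = pd.DataFrame(
            {"t": np.concatenate(ts), "i": is_, "j": js}
        )
    else:
        contacts = pd.DataFrame(columns=["t", "i", "j"])
    contacts = canonicalize_contacts(contacts)

    truth = {
        "expected_pair_hours": expected_pair_hours(scenario),
        "homophily_schedule": dict(scenario.homophily_schedule),
        "activity_schedule": dict(scenario.activity_schedule),
        "p_nonwear": scenario.p_nonwear,
        "nonwear_person_days": nonwear_days,
        "work_room_of": work_room,
        "home_area_of": home_area,
    }
    return contacts, truth


def expected_pair_hours(scenario: CrewScenario) -> dict[str, dict[str, float]]:
    """Analytic expectation of recorded person-pair contact hours.

    Per co-present day the expected recorded slot count for a pair is the sum
    over blocks of ``n_slots * P(both attend the same room) * p_pair``, damped
    by both members wearing their sensors: ``(1 - p_nonwear)^2``.
    """
    groups = scenario.all_persons()
    spans = scenario.presence()
    work_room = scenario.work_room_of()
    worn2 = (1.0 - scenario.p_nonwear) ** 2
    out: dict[str, dict[str, float]] = {}
    for window in scenario.windows:
        wave = window.label
        present = [
            p for p in sorted(groups)
            if spans[p][0] <= window.start_day and spans[p][1] >= window.end_day - 1
        ]
        wave_out: dict[str, float] = {}
        for a, b in itertools.combinations(present, 2):
            same = groups[a] == groups[b]
            slots = 0.0
            for block in scenario.blocks:
                p_pair = _pair_probability(scenario, block, same, wave)
                if block.kind == "meal":
                    p_meet = scenario.p_meal_attend**2
                elif block.kind == "work":
                    if work_room[a] != work_room[b]:
                        continue
                    p_meet = scenario.p_work_attend**2
                else:
                    p_meet = (
                        scenario.p_evening_lounge * scenario.activity_schedule[wave]
                    ) ** 2
                slots += block.n_slots * p_meet * p_pair
            hours = slots * worn2 * window.n_days * RESOLUTION / 3600.0
            wave_out[f"{a}|{b}"] = hours
        out[wave] = wave_out
    return out


# -- questionnaires ----------------------------------------------------------


def active_waves(scenario: CrewScenario, person: str) -> list[str]:
    spans = scenario.presence()
    return [
        w.label
        for w in scenario.windows
        if spans[person][0] <= w.start_day and spans[person][1] >= w.end_day - 1
    ]


def _battery_outcomes(battery: str) -> tuple[str, ...]:
    return {
        "individual": INDIVIDUAL_BATTERY,
        "team": TEAM_BATTERY,
        "all": INDIVIDUAL_BATTERY + TEAM_BATTERY,
    }[battery]


def simulate_questionnaires(
    scenario: CrewScenario,
    params: Mapping[str, GrowthParams] | None = None,
    sensor_strength: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the scored outcome panel from the linear growth model.

    ``score_pt = (beta0 + u0_p) + (beta1 + u1_p) * t + eps_pt`` with wave index
    time coding, truncated to the scale's score range. When ``sensor_strength``
    (tidy ``person_id, wave, strength``) is given, outcomes with a nonzero
    ``coupling`` draw residuals correlated with the person's standardized
    strength deviation at that wave, inducing a known within-person monotone
    association for the correlation stage to recover.

    Returns the tidy panel ``(person_id, wave, outcome, score)`` and a truth
    dict of generative parameters and applied missingness.
    """
    rng = rng or np.random.default_rng(scenario.seed + 1)
    params = params or dict(DEFAULT_GROWTH_PARAMS)
    scales = default_scales()
    groups = scenario.all_persons()
    persons = sorted(groups)
    missing = {
        (p, w): _battery_outcomes(batt) for p, w, batt in scenario.missing_waves
    }

    z_strength: dict[tuple[str, str], float] = {}
    if sensor_strength is not None:
        s = sensor_strength.copy()
        s["dev"] = s["strength"] - s.groupby("person_id")["strength"].transform("mean")
        sd = s["dev"].std(ddof=1)
        if sd > 0:
            s["z"] = s["dev"] / sd
            z_strength = {
                (r.person_id, r.wave): float(r.z) for r in s.itertuples()
            }

    wave_index = {label: float(k) for k, (label, _) in enumerate(scenario.deployments)}
    records = []
    for outcome, par in params.items():
        if outcome in ("conflict_task", "conflict_relationship"):
            continue
        lo, hi = _score_bounds(outcome, scales)
        for person in persons:
            u0 = rng.normal(0.0, par.sd_intercept)
            u1 = rng.normal(0.0, par.sd_slope)
            severe = (
                scenario.severe_paranoia_person == person
                and outcome in ("ideas_of_reference", "persecutory")
            )
            for wave in active_waves(scenario, person):
                if outcome in missing.get((person, wave), ()):
                    continue
                t = wave_index[wave]
                noise = rng.normal()
                c = par.coupling
                z = z_strength.get((person, wave))
                if c != 0.0 and z is not None:
                    eps = par.sd_resid * (c * z + np.sqrt(1 - c**2) * noise)
                else:
                    eps = par.sd_resid * noise
                score = (par.beta0 + u0) + (par.beta1 + u1) * t + eps
                if int(t) < len(par.wave_effects):
                    score += par.wave_effects[int(t)]
                if severe and t >= 2:
                    # severe paranoid ideation emerging at the polar-night wave
                    score += scenario.severe_paranoia_shift
                records.append((person, wave, outcome, float(np.clip(score, lo, hi))))
    panel = pd.DataFrame(records, columns=["person_id", "wave", "outcome", "score"])
    truth = {
        "growth_params": {k: asdict(v) for k, v in params.items()},
        "time_coding": "wave_index",
        "missing_waves": list(scenario.missing_waves),
        "severe_paranoia_person": scenario.severe_paranoia_person,
    }
    return panel, truth


def _score_bounds(outcome: str, scales: Mapping[str, ScaleDefinition]) -> tuple[float, float]:
    if outcome == "conflict":
        return scales["conflict_task"].score_range
    return scales[outcome].score_range


def expand_items(
    panel: pd.DataFrame,
    scales: Mapping[str, ScaleDefinition] | None = None,
    alpha_targets: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
    conflict_split_sd: float = 0.15,
) -> pd.DataFrame:
    """Expand scored outcomes into item-level responses at a target alpha.

    Items follow a parallel one-factor model: each item's true score is the
    outcome score mapped onto the item metric, plus item noise whose variance
    is solved per wave from the target alpha (inter-item correlation
    ``rho = alpha / (k - alpha (k - 1))`` so ``sigma_e^2 = var(T) (1-rho)/rho``),
    then rounded and clipped to the option range. Summed/averaged back, the
    items reproduce the input score without attenuation in expectation.

    The overall conflict score is first split into task and relationship
    subscale true scores by adding opposite-signed half-gaps of SD
    ``conflict_split_sd``.
    """
    rng = rng or np.random.default_rng(0)
    scales = scales or default_scales()
    alpha_targets = alpha_targets or dict(DEFAULT_ALPHA_TARGETS)

    work = panel.copy()
    conflict = work[work["outcome"] == "conflict"]
    if not conflict.empty:
        halves = []
        for r in conflict.itertuples():
            gap = rng.normal(0.0, conflict_split_sd)
            lo, hi = scales["conflict_task"].score_range
            halves.append((r.person_id, r.wave, "conflict_task", np.clip(r.score + gap, lo, hi)))
            halves.append(
                (r.person_id, r.wave, "conflict_relationship", np.clip(r.score - gap, lo, hi))
            )
        work = pd.concat(
            [
                work[work["outcome"] != "conflict"],
                pd.DataFrame(halves, columns=work.columns),
            ],
            ignore_index=True,
        )

    rows = []
    for (outcome, wave), sub in work.groupby(["outcome", "wave"]):
        sdef = scales[outcome]
        k = sdef.n_items
        alpha = alpha_targets.get(outcome, 0.9)
        rho = alpha / (k - alpha * (k - 1))
        T = sub["score"].to_numpy(dtype=float)
        T_item = T / k if sdef.aggregation == "sum" else T
        var_T = T_item.var(ddof=1) if len(T_item) > 1 else 0.0
        sigma_e = np.sqrt(var_T * (1 - rho) / rho) if var_T > 0 else 0.0
        lo, hi = sdef.option_range
        noise = rng.normal(0.0, sigma_e or 1e-9, size=(len(T_item), k))
        items = np.clip(np.rint(T_item[:, None] + noise), lo, hi).astype(int)
        for row_idx, r in enumerate(sub.itertuples()):
            for item_idx in range(k):
                rows.append(
                    (r.person_id, r.wave, outcome, item_idx + 1, items[row_idx, item_idx])
                )
    return pd.DataFrame(
        rows, columns=["person_id", "wave", "scale_id", "item_index", "response"]
    ).sort_values(["person_id", "wave", "scale_id", "item_index"]).reset_index(drop=True)


# -- full bundles ------------------------------------------------------------


def make_reference_fixture(
    seed: int = 7,
    out_dir: str | Path | None = None,
    scenario: CrewScenario | None = None,
    item_level: bool = True,
) -> dict:
    """Generate a complete, reproducible mission bundle.

    Same seed, same bundle: contacts, roster, windows, questionnaire responses
    and the ground truth. With ``out_dir`` the bundle is written as
    ``contacts.tsv``, ``roster.csv``, ``windows.csv``, ``responses.csv`` and
    ``truth.json``.
    """
    scenario = scenario or CrewScenario(seed=seed)
    rng = np.random.default_rng(seed)
    contacts, contact_truth = simulate_contacts(scenario, rng)
    roster = make_roster(scenario)
    windows = scenario.windows

    # per-deployment strength feeds the questionnaire coupling
    from .networks import aggregate_graph, strength_table

    strength_rows = []
    for w in windows:
        G = aggregate_graph(contacts, w, roster)
        st = strength_table(G, include_rooms=True)
        for p in roster.index[roster["kind"] == "person"]:
            if p in st.index:
                strength_rows.append((p, w.label, float(st[p])))
    sensor_strength = pd.DataFrame(strength_rows, columns=["person_id", "wave", "strength"])

    panel, q_truth = simulate_questionnaires(
        scenario, sensor_strength=sensor_strength, rng=rng
    )
    responses = expand_items(panel, rng=rng) if item_level else None

    truth = {**contact_truth, "questionnaires": q_truth, "seed": seed}
    bundle = {
        "scenario": scenario,
        "contacts": contacts,
        "roster": roster,
        "windows": windows,
        "panel": panel,
        "responses": responses,
        "sensor_strength": sensor_strength,
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_contacts(contacts, out / "contacts.tsv")
        write_roster(roster, out / "roster.csv")
        write_windows(windows, out / "windows.csv")
        if responses is not None:
            write_responses(responses, out / "responses.csv")
        panel.to_csv(out / "panel_true.csv", index=False)
        serializable = dict(truth)
        serializable["nonwear_person_days"] = [
            [p, int(d)] for p, d in truth["nonwear_person_days"]
        ]
        (out / "truth.json").write_text(json.dumps(serializable, indent=1, sort_keys=True))
    return bundle
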