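"""Exclusion cascade, hourly energy profiles and chrono-nutrition indicators.

The clustering object is a 24-bin vector of hourly *proportions* of
daily energy.  Main meals are standardized to fixed hour windows
(breakfast {6,7,8}, lunch {11,12,13}, dinner {17,18,19}, energy spread
uniformly across the window's bins); snacks keep their reported hour.
Chrono indicators (eating window, midpoint, window shares) instead use
the *reported* clock times of every occasion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: hour bins receiving each standardized main meal (uniform split)
MEAL_WINDOW_BINS: dict[str, tuple[int, ...]] = {
    "breakfast": (6, 7, 8),
    "lunch": (11, 12, 13),
    "dinner": (17, 18, 19),
}

#: clock-window partition of the day used for energy shares, in minutes.
#: morning 04:00-10:59, daytime 11:00-16:59, evening 17:00-03:59 (wraps)
MORNING = (240, 660)
DAYTIME = (660, 1020)

SEX_ENERGY_CAPS = {"male": 6000.0, "female": 5000.0}
ENERGY_FLOOR = 500.0


def parse_hhmm(t: str | int | float) -> int:
    """Clock time -> minutes since midnight.  Accepts 'HH:MM' or minutes."""
    if isinstance(t, (int, float, np.integer, np.floating)):
        m = int(t)
    else:
        hh, mm = str(t).split(":")
        m = int(hh) * 60 + int(mm)
    if not 0 <= m <= 1439:
        raise ValueError(f"clock time out of range: {t!r}")
    return m


def _with_minutes(occasions: pd.DataFrame) -> pd.DataFrame:
    occ = occasions.copy()
    if "clock_min" not in occ.columns:
        occ["clock_min"] = occ["time_hhmm"].map(parse_hhmm)
    return occ


def daily_energy(occasions: pd.DataFrame) -> pd.Series:
    """Total recalled energy (kcal) per person."""
    return occasions.groupby("person_id")["energy_kcal"].sum()


@dataclass
class ExclusionLog:
    """Counts removed at each (ordered) step of the exclusion cascade."""

    input_n: int
    removed: dict[str, int] = field(default_factory=dict)
    retained_n: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"input_n": self.input_n, "removed": self.removed,
                       "retained_n": self.retained_n}, fh, indent=2)


FRAILTY_INPUT_COLS = ["weight_loss_kg", "stress_level", "eq5d_mobility", "eq5d_usual"]


def apply_exclusions(
    participants: pd.DataFrame,
    occasions: pd.DataFrame,
    *,
    min_age: int = 65,
    energy_floor: float = ENERGY_FLOOR,
    energy_caps: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLog]:
    """Ordered exclusion cascade.

    Drops, in order: age < ``min_age``; no recall occasions; implausible
    daily energy (strictly below the floor or strictly above the
    sex-specific cap: 5000 kcal women, 6000 kcal men); missing frailty
    inputs (any of grip trials, weight loss, stress, EQ-5D mobility or
    usual-activities).  Boundary values (exactly 500/5000/6000 kcal) are
    retained, matching the strict inequalities of the published rule.
    """
    caps = dict(SEX_ENERGY_CAPS if energy_caps is None else energy_caps)
    unknown = set(participants["sex"].unique()) - set(caps)
    if unknown:
        raise ValueError(f"unknown sex code(s): {sorted(unknown)}")

    log = ExclusionLog(input_n=len(participants))
    df = participants

    keep = df["age"] >= min_age
    log.removed["age"] = int((~keep).sum())
    df = df[keep]

    energy = daily_energy(occasions)
    has_recall = df["person_id"].isin(energy.index)
    log.removed["no_recall"] = int((~has_recall).sum())
    df = df[has_recall]

    e = df["person_id"].map(energy)
    cap = df["sex"].map(caps)
    plausible = (e >= energy_floor) & (e <= cap)
    log.removed["implausible_energy"] = int((~plausible).sum())
    df = df[plausible]

    grip_ok = df[["grip1", "grip2", "grip3"]].notna().any(axis=1)
    frailty_ok = df[FRAILTY_INPUT_COLS].notna().all(axis=1) & grip_ok
    log.removed["missing_frailty"] = int((~frailty_ok).sum())
    df = df[frailty_ok]

    log.retained_n = len(df)
    occ = occasions[occasions["person_id"].isin(df["person_id"])]
    return df.reset_index(drop=True), occ.reset_index(drop=True), log


def build_hourly_profile(occasions: pd.DataFrame) -> np.ndarray:
    """24-bin proportion-of-daily-energy profile for one person's recall.

    Main-meal energy is spread uniformly over the standardized window
    bins regardless of reported time; each snack's energy goes wholly to
    bin ``floor(clock_time/60)``.  Bins are normalized by total energy.
    """
    occ = _with_minutes(occasions)
    total = float(occ["energy_kcal"].sum())
    if total <= 0:
        raise ValueError("undefined profile: zero total daily energy")
    bins = np.zeros(24)
    for _, row in occ.iterrows():
        kind, e = row["occasion_type"], float(row["energy_kcal"])
        if kind in MEAL_WINDOW_BINS:
            hours = MEAL_WINDOW_BINS[kind]
            for h in hours:
                bins[h] += e / len(hours)
        else:
            bins[int(row["clock_min"]) // 60] += e
    return bins / total


def hourly_profiles(occasions: pd.DataFrame) -> pd.DataFrame:
    """Profiles for every person; rows indexed by person_id, 24 columns.

    Vectorized equivalent of per-person :func:`build_hourly_profile`.
    """
    occ = _with_minutes(occasions)
    is_meal = occ["occasion_type"].isin(MEAL_WINDOW_BINS)
    parts = []
    for kind, hours in MEAL_WINDOW_BINS.items():
        sub = occ[occ["occasion_type"] == kind]
        for h in hours:
            parts.append(pd.DataFrame({
                "person_id": sub["person_id"],
                "hour": h,
                "energy": sub["energy_kcal"] / len(hours),
            }))
    snacks = occ[~is_meal]
    parts.append(pd.DataFrame({
        "person_id": snacks["person_id"],
        "hour": snacks["clock_min"] // 60,
        "energy": snacks["energy_kcal"],
    }))
    long = pd.concat(parts, ignore_index=True)
    wide = long.pivot_table(index="person_id", columns="hour", values="energy",
                            aggfunc="sum", fill_value=0.0)
    wide = wide.reindex(columns=range(24), fill_value=0.0)
    totals = wide.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"undefined profile (zero total energy) for: {bad[:5]}")
    prof = wide.div(totals, axis=0)
    prof.columns = [f"h{h:02d}" for h in range(24)]
    prof["total_energy"] = totals
    return prof


def _window_share(minutes: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    total = values.sum()
    morning = values[(minutes >= MORNING[0]) & (minutes < MORNING[1])].sum()
    daytime = values[(minutes >= DAYTIME[0]) & (minutes < DAYTIME[1])].sum()
    evening = total - morning - daytime
    if total <= 0:
        return 0.0, 0.0, 0.0
    return morning / total, daytime / total, evening / total


def chrono_indicators(occasions: pd.DataFrame) -> pd.DataFrame:
    """Per-person chrono-nutrition indicators from reported clock times.

    eating window = last - first occasion; midpoint = first + window/2;
    skip flags mark the absence of each main-meal type in the recall;
    morning/daytime/evening energy (and protein) shares use the
    04:00-10:59 / 11:00-16:59 / 17:00-03:59 partition of the day.
    """
    occ = _with_minutes(occasions)
    rows = []
    for pid, g in occ.groupby("person_id", sort=True):
        minutes = g["clock_min"].to_numpy()
        energy = g["energy_kcal"].to_numpy(dtype=float)
        protein = g["protein_g"].to_numpy(dtype=float) if "protein_g" in g else np.zeros_like(energy)
        first, last = int(minutes.min()), int(minutes.max())
        window = last - first
        me, de, ee = _window_share(minutes, energy)
        mp, dp, ep = _window_share(minutes, protein)
        kinds = set(g["occasion_type"])
        rows.append({
            "person_id": pid,
            "first_eat": first,
            "last_eat": last,
            "eating_window": window,
            "eat_midpoint": first + window / 2.0,
            "skipped_breakfast": "breakfast" not in kinds,
            "skipped_lunch": "lunch" not in kinds,
            "skipped_dinner": "dinner" not in kinds,
            "morning_share": me,
            "daytime_share": de,
            "evening_share": ee,
            "morning_share_protein": mp,
            "daytime_share_protein": dp,
            "evening_share_protein": ep,
        })
    return pd.DataFrame(rows).set_index("person_id")
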