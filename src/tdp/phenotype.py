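"""Modified Fried frailty phenotype, Healthy-Eating-Index scoring, and
covariate codings.

Frailty uses five binary criteria; three or more mark a participant as
frail:

* weight loss: self-reported unintentional loss >= 3 kg in the past year
* weakness: maximal grip strength (best of up to three trials) below
  28 kg (men) / 18 kg (women), strict inequality
* exhaustion: top stress category ("felt very much stressed", coded 1)
* slowness: some/extreme problems on the EQ-5D mobility domain
* low activity: some/extreme problems on the EQ-5D usual-activities domain

The HEI machinery is fully parameterized: every component carries its
anchors and maximum points in a standards mapping (YAML-loadable).  The
shipped default standards are a *synthetic stand-in* totalling 100
points with the conventional adequacy / moderation / balance structure;
they are not the official Korean HEI cutoffs, which must be supplied by
the user when exact scores matter.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

GRIP_CUTOFF = {"male": 28.0, "female": 18.0}
WEIGHT_LOSS_CUTOFF_KG = 3.0
STRESS_TOP_CATEGORY = 1


def frailty_components(participants: pd.DataFrame) -> pd.DataFrame:
    """Score the five Fried criteria for every participant.

    Expects columns: sex, grip1..grip3, weight_loss_kg, stress_level,
    eq5d_mobility, eq5d_usual.  Returns per-person booleans, the
    criteria count and the frail flag (count >= 3).
    """
    unknown = set(participants["sex"].unique()) - set(GRIP_CUTOFF)
    if unknown:
        raise ValueError(f"unknown sex code(s): {sorted(unknown)}")
    grip = participants[["grip1", "grip2", "grip3"]].max(axis=1, skipna=True)
    incomplete = (
        participants[["grip1", "grip2", "grip3"]].isna().all(axis=1)
        | participants[["weight_loss_kg", "stress_level", "eq5d_mobility", "eq5d_usual"]].isna().any(axis=1)
    )
    cutoff = participants["sex"].map(GRIP_CUTOFF)
    out = pd.DataFrame({
        "person_id": participants["person_id"],
        "weight_loss": participants["weight_loss_kg"] >= WEIGHT_LOSS_CUTOFF_KG,
        "weakness": grip < cutoff,
        "exhaustion": participants["stress_level"] == STRESS_TOP_CATEGORY,
        "slowness": participants["eq5d_mobility"] >= 2,
        "low_activity": participants["eq5d_usual"] >= 2,
        "incomplete": incomplete,
    })
    out["n_criteria"] = out[["weight_loss", "weakness", "exhaustion", "slowness", "low_activity"]].sum(axis=1)
    out["frail"] = out["n_criteria"] >= 3
    return out.set_index("person_id")


def categorize_activity(met_min_per_week: float) -> str:
    """GPAQ category: low < 600, moderate 600-2999, high >= 3000 MET-min/week."""
    met = float(met_min_per_week)
    if met < 0:
        raise ValueError("MET-minutes must be non-negative")
    if met < 600:
        return "low"
    if met < 3000:
        return "moderate"
    return "high"


def code_covariates(participants: pd.DataFrame) -> pd.DataFrame:
    """Analysis covariate codings: age group, sleep and activity
    categories alongside pass-through sociodemographics."""
    sleep = participants["sleep_hours"]
    sleep_cat = pd.Series(np.select([sleep < 6, sleep <= 8], ["short", "normal"], "long"),
                          index=participants.index)
    return pd.DataFrame({
        "person_id": participants["person_id"],
        "age_75plus": (participants["age"] >= 75).astype(int),
        "female": (participants["sex"] == "female").astype(int),
        "income_quartile": participants["income_quartile"],
        "education": participants["education"],
        "employed": participants["employed"],
        "living_alone": participants["living_alone"],
        "alcohol": participants["alcohol"],
        "smoking": participants.get("smoking", 0),
        "sleep_category": sleep_cat,
        "activity_category": participants["met_min_week"].map(categorize_activity),
    }).set_index("person_id")


# ---------------------------------------------------------------------------
# Healthy Eating Index


def default_hei_standards() -> dict:
    """Synthetic stand-in standards: 12 components, 100 points.

    Adequacy components interpolate linearly from 0 points at/below the
    ``zero`` anchor to ``max`` points at/above the ``full`` anchor;
    moderation components are reversed (full credit at/below ``healthy``,
    zero at/above ``unhealthy``); balance components give full credit
    inside ``band`` and decline linearly to zero at distance ``zero_at``
    outside it.
    """
    return {
        "breakfast": {"type": "adequacy", "zero": 0.0, "full": 1.0, "max": 10.0},
        "whole_grains": {"type": "adequacy", "zero": 0.0, "full": 3.0, "max": 5.0},
        "fruits": {"type": "adequacy", "zero": 0.0, "full": 2.0, "max": 10.0},
        "vegetables": {"type": "adequacy", "zero": 0.0, "full": 5.0, "max": 10.0},
        "protein_foods": {"type": "adequacy", "zero": 0.0, "full": 2.5, "max": 10.0},
        "dairy": {"type": "adequacy", "zero": 0.0, "full": 1.0, "max": 10.0},
        "sodium_mg": {"type": "moderation", "healthy": 2000.0, "unhealthy": 6000.0, "max": 10.0},
        "sat_fat_pct": {"type": "moderation", "healthy": 7.0, "unhealthy": 15.0, "max": 10.0},
        "added_sugars_pct": {"type": "moderation", "healthy": 10.0, "unhealthy": 25.0, "max": 10.0},
        "carb_pct": {"type": "balance", "band": [55.0, 65.0], "zero_at": 20.0, "max": 5.0},
        "fat_pct": {"type": "balance", "band": [15.0, 30.0], "zero_at": 15.0, "max": 5.0},
        "energy_adequacy": {"type": "balance", "band": [0.75, 1.25], "zero_at": 0.5, "max": 5.0},
    }


def load_hei_standards(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _component_score(value: float, spec: dict) -> float:
    kind = spec["type"]
    mx = float(spec["max"])
    if kind == "adequacy":
        lo, hi = float(spec["zero"]), float(spec["full"])
        if hi <= lo:
            raise ValueError("adequacy anchors must satisfy full > zero")
        return mx * float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))
    if kind == "moderation":
        lo, hi = float(spec["healthy"]), float(spec["unhealthy"])
        if hi <= lo:
            raise ValueError("moderation anchors must satisfy unhealthy > healthy")
        return mx * float(np.clip((hi - value) / (hi - lo), 0.0, 1.0))
    if kind == "balance":
        lo, hi = map(float, spec["band"])
        d0 = float(spec["zero_at"])
        dist = max(lo - value, 0.0, value - hi)
        return mx * float(np.clip(1.0 - dist / d0, 0.0, 1.0))
    raise ValueError(f"unknown component type: {kind!r}")


def hei_score(daily_summary: dict | pd.Series, standards: dict | None = None,
              missing: str = "zero") -> dict:
    """Score one person-day against the standards.

    ``daily_summary`` maps component names to intake values (servings,
    mg, % of energy, ratio...).  Missing components score 0 when
    ``missing='zero'`` (default) or raise when ``missing='error'``.
    Returns per-component scores plus adequacy/moderation/balance
    subtotals and the total.
    """
    standards = standards if standards is not None else default_hei_standards()
    scores: dict[str, float] = {}
    subtotals = {"adequacy": 0.0, "moderation": 0.0, "balance": 0.0}
    for name, spec in standards.items():
        if name not in daily_summary or pd.isna(daily_summary[name]):
            if missing == "error":
                raise ValueError(f"missing nutrient field: {name}")
            scores[name] = 0.0
        else:
            scores[name] = _component_score(float(daily_summary[name]), spec)
        subtotals[spec["type"]] += scores[name]
    scores["adequacy_subtotal"] = subtotals["adequacy"]
    scores["moderation_subtotal"] = subtotals["moderation"]
    scores["balance_subtotal"] = subtotals["balance"]
    scores["total"] = sum(subtotals.values())
    return scores
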