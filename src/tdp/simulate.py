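"""Synthetic KNHANES-like cohort generator.

Emulates the structure of a national nutrition-survey extract for older
adults: one participant table (sociodemographics, grip strength, EQ-5D
levels, survey design variables) and one eating-occasion table (meal
type, clock time, energy, protein), with *planted* ground truth:

* five archetypal within-day energy distributions (balanced, steady,
  midday, evening, morning-evening) mixed in the published proportions,
  with cluster-specific meal-skipping rates;
* a latent standardized log-energy scale ``zE`` and diet-quality scale
  ``zH`` shifted per cluster (the mediators);
* a frailty outcome drawn from a logistic model on cluster membership,
  ``zE``, ``zH`` and covariates, whose five raw Fried criteria are then
  constructed so that re-scoring the raw fields reproduces the planted
  flag exactly;
* a stratified multi-PSU design with log-normal weight variation.

Everything is deterministic given ``GeneratorConfig.seed``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

CLUSTER_NAMES = ("balanced", "steady", "midday", "evening", "morning_evening")
MEALS = ("breakfast", "lunch", "dinner")
OCCASION_TYPES = MEALS + ("snack",)

# Standard meal windows in minutes since midnight (inclusive start,
# exclusive end): breakfast 06:00-08:59, lunch 11:00-13:59, dinner
# 17:00-19:59.  Reported meal times are drawn uniformly inside these.
MEAL_TIME_WINDOWS = {"breakfast": (360, 540), "lunch": (660, 840), "dinner": (1020, 1200)}

PARTICIPANT_COLUMNS = [
    "person_id", "age", "sex", "grip1", "grip2", "grip3", "weight_loss_kg",
    "stress_level", "eq5d_mobility", "eq5d_selfcare", "eq5d_usual",
    "eq5d_pain", "eq5d_anxiety", "eq5d_index", "met_min_week",
    "income_quartile", "education", "employed", "living_alone", "alcohol",
    "smoking", "sleep_hours", "hei", "stratum", "psu", "weight",
]
OCCASION_COLUMNS = ["person_id", "occasion_type", "time_hhmm", "energy_kcal", "protein_g"]
TRUTH_COLUMNS = ["person_id", "true_cluster", "zE", "zH", "frail_prob", "frail"]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the published study conditions: cluster mix
    38.8/17.8/18.0/15.2/10.2 %, per-cluster morning/daytime/evening
    energy shares, per-cluster meal-skipping rates, and the planted
    mediation structure (evening cluster: higher energy, zE +0.17;
    morning-evening cluster: lower energy zE -0.21 and lower diet
    quality zH -0.19; both mediators protective against frailty at
    -0.27 log-odds per SD).
    """

    n_participants: int = 4184
    seed: int = 0
    cluster_mix: tuple[float, ...] = (0.388, 0.178, 0.180, 0.152, 0.102)
    # per cluster: (morning, daytime, evening) energy shares
    archetype_windows: tuple[tuple[float, float, float], ...] = (
        (0.351, 0.333, 0.326),
        (0.314, 0.401, 0.285),
        (0.227, 0.545, 0.228),
        (0.189, 0.297, 0.514),
        (0.455, 0.129, 0.416),
    )
    # per cluster: (breakfast, lunch, dinner) skip probabilities
    skip_probs: tuple[tuple[float, float, float], ...] = (
        (0.002, 0.012, 0.012),
        (0.037, 0.052, 0.085),
        (0.119, 0.007, 0.135),
        (0.179, 0.040, 0.010),
        (0.000, 0.519, 0.025),
    )
    # snack behaviour: probability of reporting a snack and its expected
    # share of daily energy; the steady cluster always has an afternoon
    # snack (15:00-16:59), other clusters snack at a uniform waking hour
    snack_prob: tuple[float, ...] = (0.20, 1.0, 0.30, 0.30, 0.30)
    snack_share: tuple[float, ...] = (0.03, 0.15, 0.04, 0.04, 0.04)
    afternoon_snack_cluster: int = 1
    # Dirichlet concentration of per-person meal shares around the
    # archetype; higher = tighter profiles
    profile_concentration: float = 60.0
    # (mu, sigma) of log daily kcal by sex
    energy_lognormal: dict = field(default_factory=lambda: {
        "male": (math.log(1900.0), 0.25),
        "female": (math.log(1500.0), 0.25),
    })
    # per-cluster shifts of the standardized mediators
    zE_shift: tuple[float, ...] = (0.0, 0.0, 0.0, 0.17, -0.21)
    zH_shift: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, -0.19)
    # frailty outcome model (log-odds)
    outcome_intercept: float = -2.0
    outcome_cluster: tuple[float, ...] = (0.0, 0.0, 0.0, 0.45, 0.36)
    outcome_zE: float = -0.27
    outcome_zH: float = -0.27
    outcome_covariates: dict = field(default_factory=lambda: {"age_75plus": 0.6, "female": 0.25})
    # confounding switch: when True, covariates are drawn independently
    # of cluster so association tests isolate the planted effects
    independent_covariates: bool = True
    # survey design
    n_strata: int = 16
    psus_per_stratum: int = 8
    weight_cv: float = 0.4

    def validate(self) -> None:
        mix = np.asarray(self.cluster_mix, dtype=float)
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError(f"cluster_mix must sum to 1, got {mix.sum():.12f}")
        if (mix <= 0).any():
            raise ValueError("cluster_mix entries must be > 0")
        skips = np.asarray(self.skip_probs, dtype=float)
        if ((skips < 0) | (skips > 1)).any():
            raise ValueError("skip_probs must lie in [0, 1]")
        for sex, (_, sigma) in self.energy_lognormal.items():
            if sigma <= 0:
                raise ValueError(f"energy sigma must be > 0 (sex={sex})")
        if self.weight_cv < 0:
            raise ValueError("weight_cv must be >= 0")
        if self.profile_concentration <= 0:
            raise ValueError("profile_concentration must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        def tupled(v):
            if isinstance(v, list):
                return tuple(tupled(x) for x in v)
            if isinstance(v, dict):
                return {k: tupled(x) for k, x in v.items()}
            return v
        cfg = cls(**{k: tupled(v) for k, v in raw.items()})
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        def listed(v):
            if isinstance(v, tuple):
                return [listed(x) for x in v]
            if isinstance(v, dict):
                return {k: listed(x) for k, x in v.items()}
            return v
        raw = {k: listed(getattr(self, k)) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class SyntheticCohort:
    """Generated tables: participants, eating occasions, and the truth."""

    participants: pd.DataFrame
    occasions: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


def default_config(n_participants: int = 4184, seed: int = 0, *, low_noise: bool = False) -> GeneratorConfig:
    """Published study conditions; ``low_noise=True`` isolates the five
    archetypal within-day *shapes* by switching off the behavioural
    noise sources (stochastic meal skipping and casual random-hour
    snacking; the steady cluster keeps its defining afternoon snack)
    and tightening the per-person meal-share Dirichlet (concentration
    300 instead of 60).  Used for clustering-recovery experiments where
    the planted archetype is the ground truth."""
    cfg = GeneratorConfig(n_participants=n_participants, seed=seed)
    if low_noise:
        cfg = replace(
            cfg,
            profile_concentration=300.0,
            skip_probs=tuple(tuple(0.0 for _ in row) for row in cfg.skip_probs),
            snack_prob=tuple(p if p == 1.0 else 0.0 for p in cfg.snack_prob),
        )
    cfg.validate()
    return cfg


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Sociodemographics with marginals loosely matching the published
    cohort (mean age ~73, 57% women, bottom-heavy income)."""
    age = np.clip(np.round(rng.normal(73.5, 6.5, n)), 65, 95).astype(int)
    female = rng.random(n) < 0.571
    income = rng.choice([1, 2, 3, 4], size=n, p=[0.469, 0.274, 0.152, 0.105])
    education = rng.choice([1, 2, 3], size=n, p=[0.696, 0.183, 0.121])
    employed = (rng.random(n) < 0.317).astype(int)
    living_alone = (rng.random(n) < 0.219).astype(int)
    alcohol = (rng.random(n) < 0.347).astype(int)
    smoking = (rng.random(n) < 0.084).astype(int)
    sleep = np.clip(np.round(rng.normal(7.2, 1.3, n), 1), 3.0, 12.0)
    act = rng.choice([0, 1, 2], size=n, p=[0.715, 0.254, 0.031])
    met = np.where(act == 0, rng.uniform(0, 600, n),
                   np.where(act == 1, rng.uniform(600, 3000, n), rng.uniform(3000, 6000, n)))
    return pd.DataFrame({
        "age": age,
        "sex": np.where(female, "female", "male"),
        "income_quartile": income,
        "education": education,
        "employed": employed,
        "living_alone": living_alone,
        "alcohol": alcohol,
        "smoking": smoking,
        "sleep_hours": sleep,
        "met_min_week": np.round(met, 1),
    })


def _frailty_fields(frail: np.ndarray, female: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Inverse construction of the five raw Fried inputs.

    Draw the criteria count conditional on the planted frail flag
    (>=3 criteria iff frail), pick which criteria are met, then set raw
    fields on the correct side of each published cutoff so the scoring
    module recovers the flag exactly.
    """
    n = frail.size
    n_crit = np.where(
        frail,
        rng.choice([3, 4, 5], size=n, p=[0.70, 0.25, 0.05]),
        rng.choice([0, 1, 2], size=n, p=[0.45, 0.35, 0.20]),
    )
    # which criteria: random subset of the 5 flags of size n_crit
    order = np.argsort(rng.random((n, 5)), axis=1)
    flags = order < n_crit[:, None]  # columns: wl, weak, exh, slow, low_act
    wl, weak, exh, slow, lowact = flags.T

    weight_loss = np.where(wl, 3.0 + rng.exponential(2.0, n), rng.uniform(0.0, 2.9, n))
    cutoff = np.where(female, 18.0, 28.0)
    grip_max = np.where(weak,
                        np.clip(cutoff - rng.uniform(1.0, 8.0, n), 5.0, None),
                        cutoff + rng.uniform(0.5, 12.0, n))
    # three trials whose maximum equals grip_max
    drop = rng.uniform(0.0, 2.0, (n, 2))
    trials = np.column_stack([grip_max, grip_max - drop[:, 0], grip_max - drop[:, 1]])
    # shuffle trial order per row
    perm = np.argsort(rng.random((n, 3)), axis=1)
    trials = np.take_along_axis(trials, perm, axis=1)

    stress = np.where(exh, 1, rng.choice([2, 3, 4], size=n, p=[0.35, 0.45, 0.20]))
    mobility = np.where(slow, rng.choice([2, 3], size=n, p=[0.85, 0.15]), 1)
    usual = np.where(lowact, rng.choice([2, 3], size=n, p=[0.85, 0.15]), 1)
    other = rng.choice([1, 2, 3], size=(n, 3), p=[0.80, 0.15, 0.05])
    levels_sum = (mobility - 1) + (usual - 1) + (other - 1).sum(axis=1)
    eq5d_index = np.clip(1.0 - 0.06 * levels_sum - rng.normal(0.0, 0.02, n), 0.0, 1.0)

    return pd.DataFrame({
        "grip1": np.round(trials[:, 0], 1),
        "grip2": np.round(trials[:, 1], 1),
        "grip3": np.round(trials[:, 2], 1),
        "weight_loss_kg": np.round(weight_loss, 1),
        "stress_level": stress,
        "eq5d_mobility": mobility,
        "eq5d_selfcare": other[:, 0],
        "eq5d_usual": usual,
        "eq5d_pain": other[:, 1],
        "eq5d_anxiety": other[:, 2],
        "eq5d_index": np.round(eq5d_index, 3),
    })


def _occasions_for(pid: str, cluster: int, energy: float, cfg: GeneratorConfig,
                   rng: np.random.Generator) -> list[tuple]:
    """Draw the recall day for one participant: meal presence, clock
    times and the Dirichlet energy split around the cluster archetype."""
    skips = cfg.skip_probs[cluster]
    present = [rng.random() >= skips[m] for m in range(3)]
    has_snack = rng.random() < cfg.snack_prob[cluster]
    if not any(present) and not has_snack:
        present[1] = True  # a recall day records at least one occasion

    arche = np.asarray(cfg.archetype_windows[cluster], dtype=float)
    arche = arche / arche.sum()
    s = cfg.snack_share[cluster]
    if cluster == cfg.afternoon_snack_cluster:
        # the afternoon snack lives in the daytime window: carve its
        # share out of lunch so the window totals still match the
        # archetype (steady pattern: lunch + snack = daytime share)
        mean = np.array([arche[0], max(arche[1] - s, 0.02), arche[2], s])
        mean = mean / mean.sum()
    else:
        mean = np.append(arche * (1.0 - s), s)
    mask = np.array(present + [has_snack])
    mean = np.where(mask, mean, 0.0)
    mean = mean / mean.sum()
    active = np.flatnonzero(mask)
    if active.size == 1:
        shares = mask.astype(float)
    else:
        shares = np.zeros(4)
        shares[active] = rng.dirichlet(cfg.profile_concentration * mean[active])

    rows = []
    for m, meal in enumerate(MEALS):
        if not present[m]:
            continue
        lo, hi = MEAL_TIME_WINDOWS[meal]
        t = int(rng.integers(lo, hi))
        e = energy * shares[m]
        rows.append((pid, meal, t, e))
    if has_snack:
        if cluster == cfg.afternoon_snack_cluster:
            # archetypal afternoon-snack time: a consistent hour so the
            # steady pattern is one mode, not one per profile bin
            t = int(rng.integers(900, 960))  # 15:00-15:59
        else:
            t = int(rng.integers(360, 1320))  # uniform waking hour
        rows.append((pid, "snack", t, energy * shares[3]))
    return rows


def generate(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given the seed."""
    cfg = config if config is not None else default_config()
    cfg.validate()
    n = cfg.n_participants
    if n < 50:
        raise ValueError(f"n_participants={n} too small for a stratified multi-PSU design (need >= 50)")
    rng = np.random.default_rng(cfg.seed)

    ids = [f"P{i:06d}" for i in range(n)]
    cluster = rng.choice(len(cfg.cluster_mix), size=n, p=np.asarray(cfg.cluster_mix) / np.sum(cfg.cluster_mix))
    cov = _draw_covariates(n, rng)
    female = (cov["sex"] == "female").to_numpy()

    zE = np.asarray(cfg.zE_shift)[cluster] + rng.standard_normal(n)
    zH = np.asarray(cfg.zH_shift)[cluster] + rng.standard_normal(n)
    mu = np.where(female, cfg.energy_lognormal["female"][0], cfg.energy_lognormal["male"][0])
    sigma = np.where(female, cfg.energy_lognormal["female"][1], cfg.energy_lognormal["male"][1])
    energy = np.exp(mu + sigma * zE)
    hei = np.clip(50.0 + 10.0 * zH, 0.0, 100.0)

    eta = (cfg.outcome_intercept
           + np.asarray(cfg.outcome_cluster)[cluster]
           + cfg.outcome_zE * zE + cfg.outcome_zH * zH
           + cfg.outcome_covariates.get("age_75plus", 0.0) * (cov["age"].to_numpy() >= 75)
           + cfg.outcome_covariates.get("female", 0.0) * female)
    p_frail = 1.0 / (1.0 + np.exp(-eta))
    frail = rng.random(n) < p_frail

    frail_fields = _frailty_fields(frail, female, rng)

    # survey design: PSUs assigned round-robin; weights log-normal
    n_psus = cfg.n_strata * cfg.psus_per_stratum
    psu_global = np.arange(n) % n_psus
    stratum = psu_global // cfg.psus_per_stratum
    psu = psu_global % cfg.psus_per_stratum
    weight = 1000.0 * np.exp(rng.normal(0.0, cfg.weight_cv, n)) if cfg.weight_cv > 0 else np.full(n, 1000.0)

    occ_rows: list[tuple] = []
    for i in range(n):
        occ_rows.extend(_occasions_for(ids[i], int(cluster[i]), float(energy[i]), cfg, rng))
    occ = pd.DataFrame(occ_rows, columns=["person_id", "occasion_type", "clock_min", "energy_kcal"])
    # protein ~ 15% of occasion energy at 4 kcal/g, with mild noise
    occ["protein_g"] = np.round(occ["energy_kcal"] / 4.0 * np.clip(rng.normal(0.15, 0.03, len(occ)), 0.03, 0.35), 2)
    occ["energy_kcal"] = occ["energy_kcal"].round(1)
    occ["time_hhmm"] = occ["clock_min"].map(lambda m: f"{m // 60:02d}:{m % 60:02d}")
    occ = occ[["person_id", "occasion_type", "time_hhmm", "energy_kcal", "protein_g"]]

    participants = pd.concat([
        pd.DataFrame({"person_id": ids}),
        cov,
        frail_fields,
        pd.DataFrame({"hei": np.round(hei, 2), "stratum": stratum, "psu": psu, "weight": np.round(weight, 3)}),
    ], axis=1)[PARTICIPANT_COLUMNS]

    truth = pd.DataFrame({
        "person_id": ids,
        "true_cluster": cluster + 1,
        "zE": np.round(zE, 6),
        "zH": np.round(zH, 6),
        "frail_prob": np.round(p_frail, 6),
        "frail": frail.astype(int),
    })
    return SyntheticCohort(participants=participants, occasions=occ, truth=truth, config=cfg)


_HHMM = re.compile(r"^([01]\d|2[0-3]):([0-5]\d)$")


def _validate_occasions(occ: pd.DataFrame) -> None:
    bad = [t for t in occ["time_hhmm"] if not _HHMM.match(str(t))]
    if bad:
        raise ValueError(f"invalid clock time(s): {bad[:5]} (expected HH:MM in 00:00-23:59)")
    unknown = set(occ["occasion_type"]) - set(OCCASION_TYPES)
    if unknown:
        raise ValueError(f"unknown occasion types: {sorted(unknown)}")
    if (occ["energy_kcal"] < 0).any() or (occ["protein_g"] < 0).any():
        raise ValueError("energy and protein must be non-negative")


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write participants.csv / occasions.csv / truth.csv (+ config.yaml)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _validate_occasions(cohort.occasions)
    paths = {
        "participants": directory / "participants.csv",
        "occasions": directory / "occasions.csv",
        "truth": directory / "truth.csv",
    }
    cohort.participants[PARTICIPANT_COLUMNS].to_csv(paths["participants"], index=False)
    cohort.occasions[OCCASION_COLUMNS].to_csv(paths["occasions"], index=False)
    cohort.truth[TRUTH_COLUMNS].to_csv(paths["truth"], index=False)
    if cohort.config is not None:
        cohort.config.to_yaml(directory / "config.yaml")
        paths["config"] = directory / "config.yaml"
    return paths


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    participants = pd.read_csv(directory / "participants.csv")
    occasions = pd.read_csv(directory / "occasions.csv")
    _validate_occasions(occasions)
    truth_path = directory / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame(columns=TRUTH_COLUMNS)
    cfg_path = directory / "config.yaml"
    cfg = GeneratorConfig.from_yaml(cfg_path) if cfg_path.exists() else None
    return SyntheticCohort(participants=participants, occasions=occasions, truth=truth, config=cfg)
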