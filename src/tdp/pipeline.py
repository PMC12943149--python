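"""End-to-end orchestration: cohort -> profiles -> clusters -> frailty ->
survey-weighted associations and mediation.

The association ladder mirrors the usual three-model design:

* Model 1: cluster indicators only (reference = largest cluster,
  i.e. the balanced pattern on the planted mix);
* Model 2: + age group, sex, household income, education, employment,
  living arrangement, alcohol;
* Model 3: + standardized total energy intake and standardized HEI.

Energy enters the models on a standardized log scale (z-scored within
sex, since energy requirements differ by sex); HEI is z-scored overall.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tdp.cluster import build_kernel, cluster_profiles
from tdp.dtw import dtw_matrix
from tdp.mediation import SurveyMediation
from tdp.phenotype import code_covariates, frailty_components
from tdp.simulate import GeneratorConfig, default_config, generate, read_cohort, write_cohort
from tdp.survey import SurveyDesign, SurveyLogit
from tdp.trajectory import apply_exclusions, chrono_indicators, daily_energy, hourly_profiles
from tdp.validity import borda_consensus, validity_indices

MODEL2_COVARIATES = ["age_75plus", "female", "income_quartile", "education",
                     "employed", "living_alone", "alcohol"]
CATEGORICAL_COVARIATES = ["income_quartile", "education"]

#: default Sakoe-Chiba band (hours) for the clustering analysis.  DTW
#: should absorb modest shifts in meal timing, not warp a whole meal
#: across the day: unbanded DTW on sparse hourly profiles aligns
#: breakfast+lunch days with lunch+dinner days almost for free, erasing
#: meal identity.  A 3-hour radius keeps within-meal flexibility.
DEFAULT_BAND = 3


def standardized_mediators(participants: pd.DataFrame, occasions: pd.DataFrame) -> pd.DataFrame:
    """Standardized mediator columns: zE (log daily energy, z-scored
    within sex) and zH (HEI z-scored overall), indexed by person_id."""
    energy = daily_energy(occasions)
    loge = np.log(participants["person_id"].map(energy).astype(float))
    df = pd.DataFrame({"person_id": participants["person_id"],
                       "sex": participants["sex"], "loge": loge,
                       "hei": participants["hei"].astype(float)})
    zE = df.groupby("sex")["loge"].transform(lambda s: (s - s.mean()) / s.std(ddof=0))
    zH = (df["hei"] - df["hei"].mean()) / df["hei"].std(ddof=0)
    return pd.DataFrame({"person_id": df["person_id"], "zE": zE, "zH": zH}).set_index("person_id")


def _dummy_code(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cols = []
    for c in covariates:
        if c in CATEGORICAL_COVARIATES:
            d = pd.get_dummies(df[c].astype("category"), prefix=c, drop_first=True, dtype=float)
            cols.append(d)
        else:
            cols.append(df[[c]].astype(float))
    return pd.concat(cols, axis=1) if cols else pd.DataFrame(index=df.index)


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Map raw cluster indices to 1..K in descending cluster size, so
    cluster 1 is always the modal (balanced-type) pattern."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    mapping = {int(c): i + 1 for i, c in enumerate(order)}
    return np.asarray([mapping[int(c)] for c in labels])


def association_models(analysis: pd.DataFrame, design: SurveyDesign,
                       models: tuple[int, ...] = (1, 2, 3)) -> dict[int, "object"]:
    """Fit the Model 1-3 ladder of survey-weighted logistic regressions
    of frailty on cluster membership (cluster 1 = reference)."""
    ks = sorted(analysis["cluster"].unique())
    cluster_dummies = pd.DataFrame(
        {f"cluster{k}": (analysis["cluster"] == k).astype(float) for k in ks if k != 1},
        index=analysis.index)
    results = {}
    for m in models:
        parts = [pd.Series(1.0, index=analysis.index, name="intercept"), cluster_dummies]
        if m >= 2:
            parts.append(_dummy_code(analysis, MODEL2_COVARIATES))
        if m >= 3:
            parts.append(analysis[["zE", "zH"]].astype(float))
        X = pd.concat(parts, axis=1)
        fit = SurveyLogit(analysis["frail"].to_numpy(float), X.to_numpy(float),
                          design, exog_names=list(X.columns)).fit()
        results[m] = fit
    return results


def run_all(out_dir: str | Path, n: int = 1000, seed: int = 0,
            config: GeneratorConfig | None = None, k_range: tuple[int, int] = (2, 7),
            n_restarts: int = 20, mediation_B: int = 200, band: int | None = DEFAULT_BAND,
            cohort_dir: str | Path | None = None) -> dict:
    """Run the full pipeline, writing all artefacts under ``out_dir``.

    Either generates a synthetic cohort (default) or reads one from
    ``cohort_dir``.  Returns a dict with the main in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cohort_dir is None:
        cfg = config if config is not None else default_config(n_participants=n, seed=seed)
        cohort = generate(cfg)
        write_cohort(cohort, out / "cohort")
    else:
        cohort = read_cohort(cohort_dir)

    participants, occasions, excl = apply_exclusions(cohort.participants, cohort.occasions)
    excl.to_json(out / "exclusions.json")

    profiles = hourly_profiles(occasions)
    profiles = profiles.loc[participants["person_id"]]
    profiles.to_csv(out / "profiles.csv")
    indicators = chrono_indicators(occasions)
    indicators.to_csv(out / "indicators.csv")

    bins = profiles[[f"h{h:02d}" for h in range(24)]].to_numpy()
    dist = dtw_matrix(bins, ids=list(profiles.index), band=band)
    kernel = build_kernel(dist)

    scores, solutions = [], {}
    for K in range(k_range[0], k_range[1] + 1):
        sol = cluster_profiles(dist, K, seed=seed, n_restarts=n_restarts, kernel=kernel)
        solutions[K] = sol
        scores.append(validity_indices(dist, sol))
    consensus = borda_consensus(scores)
    consensus.table.to_csv(out / "validity.csv")
    with open(out / "consensus.json", "w") as fh:
        json.dump(consensus.to_json(), fh, indent=2)
    best = solutions[consensus.selected_K]
    labels = relabel_by_size(best.labels)
    labels_df = pd.DataFrame({"person_id": profiles.index, "cluster": labels})
    labels_df.to_csv(out / "labels.csv", index=False)
    with open(out / "solution.json", "w") as fh:
        json.dump({"K": best.K, "objective": best.objective, "seed": best.seed,
                   "n_iter": best.n_iter, "restart_index": best.restart_index,
                   "medoid_ids": [str(i) for i in best.medoid_ids]}, fh, indent=2)

    phen = frailty_components(participants)
    phen.to_csv(out / "phenotypes.csv")

    covs = code_covariates(participants)
    meds = standardized_mediators(participants, occasions)
    analysis = (participants.set_index("person_id")[["stratum", "psu", "weight"]]
                .join(phen[["frail"]]).join(covs).join(meds)
                .join(labels_df.set_index("person_id")))
    analysis["frail"] = analysis["frail"].astype(int)
    design = SurveyDesign.from_frame(analysis.reset_index())

    assoc = association_models(analysis, design)
    assoc_json = {f"model{m}": json.loads(r.odds_ratios().to_json(orient="index"))
                  for m, r in assoc.items()}
    with open(out / "associations.json", "w") as fh:
        json.dump(assoc_json, fh, indent=2)

    # mediation for the non-reference cluster with the largest Model-2 OR
    or2 = assoc[2].odds_ratios()
    cluster_terms = [t for t in or2.index if t.startswith("cluster")]
    target = max(cluster_terms, key=lambda t: or2.loc[t, "OR"])
    target_k = int(target.removeprefix("cluster"))
    sub = analysis[analysis["cluster"].isin([1, target_k])]
    sub_design = SurveyDesign.from_frame(sub.reset_index())
    med_cov = pd.concat([
        _dummy_code(sub, MODEL2_COVARIATES),
    ], axis=1)
    med = SurveyMediation(sub["frail"].to_numpy(float),
                          (sub["cluster"] == target_k).to_numpy(float),
                          sub[["zE", "zH"]].to_numpy(float),
                          covariates=med_cov.to_numpy(float),
                          design=sub_design, mediator_names=["energy", "hei"])
    med_res = med.fit(B=mediation_B, seed=seed)
    with open(out / "mediation.json", "w") as fh:
        json.dump({"exposure": target, **med_res.to_dict()}, fh, indent=2)

    return {"exclusions": excl, "profiles": profiles, "indicators": indicators,
            "consensus": consensus, "solution": best, "labels": labels_df,
            "phenotypes": phen, "associations": assoc, "mediation": med_res}
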