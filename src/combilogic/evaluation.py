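"""Synthetic benchmark studies exercising the full method.

Each study generates its own inputs from a seed, runs the package's actual
code paths and measures the outcome — they back both the test suite and the
reproduction script.  Study sizes are chosen to run on a single CPU in a few
minutes; docs/methods.md records the problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codruggability import CoDruggabilityThresholds, codruggability_table
from .combo_predict import predict_combinations
from .confirm_stats import responding_pairs
from .logic_fit import (DonorData, LogicModel, TrainingParams,
                        exhaustive_search, ga_optimize, fit_cohort)
from .normalization import normalize_dataset
from .subgroup import merge_subgroup, rank_sum_p
from .synthetic_data import (CohortSpec, NoiseModel,
                             ground_truth_identifiable, make_ground_truth,
                             random_pkn, simulate_cohort)
from .codruggability import score, score_table, select_codruggable


# ---------------------------------------------------------------------------
# Binary truth table of the co-druggability score
# ---------------------------------------------------------------------------

#: (S_healthy, S_MS, S_treatment) -> (score, co-druggable under maximal
#: healthy-vs-treated difference with forced significance)
BINARY_TRUTH_TABLE = {
    (0, 0, 0): (0, False), (0, 0, 1): (-1, True),
    (0, 1, 0): (1, False), (0, 1, 1): (0, True),
    (1, 0, 0): (0, True), (1, 0, 1): (1, False),
    (1, 1, 0): (-1, True), (1, 1, 1): (0, False),
}


def truth_table_study() -> dict:
    """Score all 8 binary activity patterns and run the selection filters.

    Returns the number of patterns whose score matches the expected value
    and the number whose co-druggable flag matches, out of 8.
    """
    rows = sorted(BINARY_TRUTH_TABLE)
    scores_ok = sum(score(*r) == BINARY_TRUTH_TABLE[r][0] for r in rows)

    def net(activity, group):
        from .logic_fit import DonorModel
        m = DonorModel(edge_weights=np.asarray(activity, float),
                       best_score=0.0, ensemble_size=1)
        return merge_subgroup([m], group,
                              hyperedge_ids=[f"e{i}" for i in range(8)])

    records = score_table(net([r[0] for r in rows], "healthy"),
                          net([r[1] for r in rows], "untreated"),
                          net([r[2] for r in rows], "treated"))
    rng = np.random.default_rng(0)
    jitter = 1e-3
    wh = np.tile([r[0] for r in rows], (6, 1)) + rng.normal(0, jitter, (6, 8))
    wt = np.tile([r[2] for r in rows], (6, 1)) + rng.normal(0, jitter, (6, 8))
    flagged = select_codruggable(records, wh, wt, CoDruggabilityThresholds(),
                                 active=np.ones(8, dtype=bool))
    flags_ok = sum(bool(f) == BINARY_TRUTH_TABLE[r][1]
                   for f, r in zip(flagged["co_druggable"], rows))
    return {"rows": len(rows), "scores_correct": int(scores_ok),
            "flags_correct": int(flags_ok)}


# ---------------------------------------------------------------------------
# Full-scale dataset cardinality
# ---------------------------------------------------------------------------

def full_scale_dataset_study(seed: int = 0) -> dict:
    """Generate the study-scale cohort: 180 donors x 20 stimuli x 17
    readouts x 3 timepoints, and count the stimulus-condition measurements."""
    pkn = random_pkn(seed=seed)  # default 20-stimulus / 17-readout panel
    spec = CohortSpec(n_donors_per_group=30,
                      groups=("healthy", "untreated", "IFNB", "GA", "NTZ",
                              "FTY"),
                      seed=seed)
    truth = make_ground_truth(pkn, spec, n_deregulated=4, seed=seed)
    cohort = simulate_cohort(truth, spec, NoiseModel())
    n_donors = len(cohort.donors)
    return {"n_donors": n_donors,
            "n_stimuli": len(cohort.stimuli),
            "n_readouts": len(cohort.readouts),
            "n_timepoints": len(cohort.timepoints),
            "measurements": cohort.measurement_count}


# ---------------------------------------------------------------------------
# GA vs exhaustive enumeration
# ---------------------------------------------------------------------------

def _small_instance(seed: int) -> tuple[LogicModel, DonorData] | None:
    rng = np.random.default_rng([seed, 5])
    stimuli = tuple(f"S{i}" for i in range(3))
    readouts = tuple(f"M{i}" for i in range(2))
    pkn = random_pkn(stimuli, readouts, n_intermediates=2, seed=seed,
                     and_gate_frac=0.3, extra_edge_frac=0.1)
    model = LogicModel(pkn)
    if model.n_hyperedges > 10:
        return None
    truth = rng.random(model.n_hyperedges) < 0.7
    conds = [frozenset([s]) for s in stimuli]
    sim = model.readout_matrix(truth, conds, list(readouts))
    values = np.where(np.nan_to_num(sim, nan=0.0) > 0, 0.8, 0.0)
    values[rng.random(values.shape) < 0.15] = np.nan
    if not np.any(np.isfinite(values)):
        return None
    return model, DonorData(conditions=conds, readouts=list(readouts),
                            values=values)


def ga_oracle_study(n_instances: int = 20, seed: int = 0) -> dict:
    """Compare the GA's best score with the exhaustive optimum on random
    networks of at most 10 hyperedges."""
    matches, tried, s = 0, 0, 0
    while tried < n_instances:
        inst = _small_instance(seed * 1000 + s)
        s += 1
        if inst is None:
            continue
        model, data = inst
        params = TrainingParams(n_runs=3, population=30, max_generations=60,
                                stall_generations=15, seed=seed + s)
        runs = ga_optimize(model, data, params)
        _, opt = exhaustive_search(model, data, params)
        matches += int(abs(min(c for _, c in runs) - opt) < 1e-12)
        tried += 1
    return {"instances": tried, "matches": matches,
            "fraction": matches / tried}


# ---------------------------------------------------------------------------
# Parameter recovery + end-to-end planted-edge detection
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    mean_jaccard: float
    min_jaccard: float
    n_donors: int
    planted_edges: set[str]
    flagged_edges: set[str]
    planted_flagged: int
    predictions: pd.DataFrame
    predictions_through_planted: int


def recovery_study(seed: int = 42, n_donors_per_group: int = 10,
                   training: TrainingParams | None = None) -> RecoveryResult:
    """Noise-free cohort: fit every donor, compare recovered active edges to
    the ground-truth identifiable sets, then run the subgroup ->
    co-druggability -> prediction cascade and check that the planted
    unreverted deregulated edges are flagged and routed to predictions."""
    stimuli = tuple(f"S{i:02d}" for i in range(6))
    readouts = tuple(f"M{i:02d}" for i in range(6))
    from .pkn import preprocess_identifiability
    pkn = random_pkn(stimuli, readouts, n_intermediates=8, seed=seed)
    pkn = preprocess_identifiability(pkn, set(stimuli), set(readouts))
    spec = CohortSpec(n_donors_per_group=n_donors_per_group,
                      groups=("healthy", "untreated", "FTY"),
                      stimuli=stimuli, readouts=readouts, seed=seed)
    truth = make_ground_truth(pkn, spec, n_deregulated=3, seed=seed,
                              n_unreverted=2)
    cohort = simulate_cohort(truth, spec,
                             NoiseModel(cv=0.0, donor_variability=0.0))
    norm = normalize_dataset(cohort)
    model = truth.model
    params = training or TrainingParams(population=40, max_generations=150,
                                        stall_generations=30, n_runs=10,
                                        seed=seed)
    donor_data = {d: norm.donor_data(d, list(stimuli), list(readouts))
                  for d in cohort.donors}
    models = fit_cohort(model, donor_data, params)

    groups = cohort.groups
    jaccards = []
    for donor, dm in models.items():
        core = ground_truth_identifiable(truth, groups[donor], spec)
        recovered = dm.edge_weights >= 0.5
        union = int((core | recovered).sum())
        inter = int((core & recovered).sum())
        jaccards.append(inter / union if union else 1.0)

    by_group = {}
    for donor, dm in models.items():
        by_group.setdefault(groups[donor], {})[donor] = dm
    nets = {g: merge_subgroup(list(ms.values()), g, model.hyperedge_ids)
            for g, ms in by_group.items()}
    wh = np.array([m.edge_weights for m in by_group["healthy"].values()])
    wt = np.array([m.edge_weights for m in by_group["FTY"].values()])
    flagged = codruggability_table(nets["healthy"], nets["untreated"],
                                   nets["FTY"], wh, wt)
    flagged_edges = set(
        flagged.loc[flagged["co_druggable"], "interaction"])
    planted = (truth.deregulated_edges["FTY"]
               & truth.deregulated_edges["untreated"])
    predictions = predict_combinations(model, nets["FTY"], flagged,
                                       list(stimuli), list(readouts))
    through = (int(predictions["interaction"].isin(planted).sum())
               if not predictions.empty else 0)
    return RecoveryResult(
        mean_jaccard=float(np.mean(jaccards)),
        min_jaccard=float(np.min(jaccards)),
        n_donors=len(models),
        planted_edges=planted,
        flagged_edges=flagged_edges,
        planted_flagged=len(planted & flagged_edges),
        predictions=predictions,
        predictions_through_planted=through)


# ---------------------------------------------------------------------------
# Type-I calibration of the statistical stages
# ---------------------------------------------------------------------------

def calibration_study(n_reps: int = 1000, seed: int = 0,
                      n_donors: int = 20, alpha: float = 0.05) -> dict:
    """Null-simulation rejection rates of the stage-1 one-sample Wilcoxon
    and of the two-sample rank-sum used for the subgroup comparisons.

    Group size defaults to 20 donors, representative of the treatment arms
    of such cohorts; at that size the discrete achievable levels of the
    exact tests lie close to the nominal alpha."""
    rng = np.random.default_rng([seed, 23])
    rows = []
    for rep in range(n_reps):
        for d in range(n_donors):
            rows.append({"donor": f"d{d}", "stimulus": f"rep{rep}",
                         "readout": "R", "fc": rng.normal(0.0, 0.5)})
    frame = pd.DataFrame(rows)
    stage1 = responding_pairs(frame, {f"d{d}": "g" for d in range(n_donors)},
                              min_donors=n_donors)
    wilcoxon_rate = float((stage1["p"] < alpha).mean())

    hits = 0
    for _ in range(n_reps):
        a = rng.normal(0.0, 1.0, n_donors)
        b = rng.normal(0.0, 1.0, n_donors)
        hits += rank_sum_p(a, b) < alpha
    half_width = 1.96 * np.sqrt(alpha * (1 - alpha) / n_reps)
    return {"n_reps": n_reps,
            "wilcoxon_type1_rate": wilcoxon_rate,
            "ranksum_type1_rate": hits / n_reps,
            "binomial_ci": (alpha - half_width, alpha + half_width)}
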