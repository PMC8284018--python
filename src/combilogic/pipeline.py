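"""End-to-end orchestration with file-based stage contracts.

Each stage reads its inputs from, and writes its outputs to, the run's
output directory, so stages can be run one by one (CLI subcommands) or all
at once with :func:`run_pipeline`, which also writes a manifest (parameter
values, seeds, input hashes, stage outputs).  A single YAML config drives
everything; every statistically ambiguous choice (filter scope, test
sidedness, thresholds) is a named key so it is visible and overridable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codruggability import CoDruggabilityThresholds, codruggability_table
from .combo_predict import predict_combinations, summarize_by_interaction
from .confirm_stats import confirm_subgroups
from .logic_fit import DonorModel, LogicModel, TrainingParams, fit_cohort
from .midas import PerturbationDataset
from .normalization import NormalizationParams, normalize_dataset
from .pkn import (PriorKnowledgeNetwork, preprocess_identifiability,
                  read_and_gates, read_annotations, read_sif, write_and_gates,
                  write_annotations, write_sif)
from .subgroup import merge_subgroup, distance_report, weights_frame
from .synthetic_data import (CohortSpec, NoiseModel, make_ground_truth,
                             random_pkn, simulate_cohort, write_ground_truth)


@dataclass
class SyntheticSpec:
    n_donors_per_group: int = 10
    groups: tuple[str, ...] = ("healthy", "untreated", "FTY")
    n_stimuli: int = 6
    n_readouts: int = 5
    n_intermediates: int = 8
    n_deregulated: int = 2
    n_unreverted: int | None = None
    effect_size: float = 4.0
    cv: float = 0.15
    donor_variability: float = 0.05


@dataclass
class PipelineConfig:
    outdir: str = "results/run"
    seed: int = 0
    pkn_sif: str | None = None
    annotations: str | None = None
    and_gates: str | None = None
    midas: str | None = None
    synthetic: SyntheticSpec | None = field(default_factory=SyntheticSpec)
    normalization: NormalizationParams = field(
        default_factory=NormalizationParams)
    training: TrainingParams = field(default_factory=lambda: TrainingParams(
        population=40, max_generations=150, stall_generations=30))
    thresholds: CoDruggabilityThresholds = field(
        default_factory=CoDruggabilityThresholds)
    healthy_group: str = "healthy"
    untreated_group: str = "untreated"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            if "groups" in syn:
                syn["groups"] = tuple(syn["groups"])
            kwargs["synthetic"] = SyntheticSpec(**syn)
        for key, klass in (("normalization", NormalizationParams),
                           ("training", TrainingParams),
                           ("thresholds", CoDruggabilityThresholds)):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = klass(**kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.synthetic is None:
            for key in ("pkn_sif", "midas"):
                path = getattr(self, key)
                if path is None:
                    raise ValueError(f"non-synthetic run requires {key}")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{key}: {path} does not exist")
        for key in ("pkn_sif", "annotations", "and_gates", "midas"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key}: {path} does not exist")


def _out(config: PipelineConfig, name: str) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out / name


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_network(config: PipelineConfig) -> PriorKnowledgeNetwork:
    sif = config.pkn_sif or _out(config, "network.sif")
    pkn = read_sif(sif)
    ann = config.annotations or _out(config, "annotations.csv")
    if Path(ann).exists():
        read_annotations(pkn, ann)
    gates = config.and_gates or _out(config, "and_gates.csv")
    if Path(gates).exists():
        read_and_gates(pkn, gates)
    return pkn


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> list[Path]:
    """Generate the synthetic cohort: network files, ground truth, MIDAS."""
    syn = config.synthetic
    if syn is None:
        raise ValueError("config has no synthetic section")
    stimuli = tuple(f"S{i:02d}" for i in range(syn.n_stimuli))
    readouts = tuple(f"M{i:02d}" for i in range(syn.n_readouts))
    pkn = random_pkn(stimuli, readouts, n_intermediates=syn.n_intermediates,
                     seed=config.seed)
    pkn = preprocess_identifiability(pkn, set(stimuli), set(readouts))
    spec = CohortSpec(n_donors_per_group=syn.n_donors_per_group,
                      groups=syn.groups, stimuli=stimuli, readouts=readouts,
                      seed=config.seed)
    truth = make_ground_truth(pkn, spec, syn.n_deregulated, seed=config.seed,
                              n_unreverted=syn.n_unreverted)
    noise = NoiseModel(effect_size=syn.effect_size, cv=syn.cv,
                       donor_variability=syn.donor_variability)
    cohort = simulate_cohort(truth, spec, noise)
    paths = [_out(config, n) for n in
             ("network.sif", "annotations.csv", "and_gates.csv",
              "ground_truth.json", "midas.csv")]
    write_sif(pkn, paths[0])
    write_annotations(pkn, paths[1])
    write_and_gates(pkn, paths[2])
    write_ground_truth(truth, paths[3])
    cohort.to_midas(paths[4])
    return paths


def stage_normalize(config: PipelineConfig) -> list[Path]:
    midas = config.midas or _out(config, "midas.csv")
    raw = PerturbationDataset.from_midas(midas)
    norm = normalize_dataset(raw, config.normalization)
    paths = [_out(config, n) for n in
             ("normalized.csv", "state_percentages.csv", "groups.csv")]
    columns = ["donor", "stimulus", "readout", "fc", "q", "state", "value"]
    norm.table[columns].to_csv(paths[0], index=False, float_format="%.6g")
    norm.state_percentages().to_csv(paths[1], float_format="%.4g")
    pd.DataFrame(sorted(raw.groups.items()),
                 columns=["donor", "group"]).to_csv(paths[2], index=False)
    return paths


def _panel(config: PipelineConfig,
           pkn: PriorKnowledgeNetwork) -> tuple[list[str], list[str]]:
    return sorted(pkn.stimuli | pkn.drugs), sorted(pkn.readouts)


def stage_fit(config: PipelineConfig) -> list[Path]:
    pkn = _load_network(config)
    model = LogicModel(pkn)
    stimuli, readouts = _panel(config, pkn)
    table = pd.read_csv(_out(config, "normalized.csv"))
    groups = pd.read_csv(_out(config, "groups.csv"))
    group_of = dict(zip(groups["donor"], groups["group"]))
    from .normalization import NormalizedDataset
    norm = NormalizedDataset(table=table, params=config.normalization)
    donor_data = {d: norm.donor_data(d, stimuli, readouts)
                  for d in sorted(group_of)}
    params = TrainingParams(**{**asdict(config.training),
                               "seed": config.seed})
    models = fit_cohort(model, donor_data, params)
    weights = pd.DataFrame(
        {d: m.edge_weights for d, m in models.items()},
        index=model.hyperedge_ids).T
    weights.index.name = "donor"
    weights.insert(0, "group", [group_of[d] for d in weights.index])
    weights.insert(1, "best_score", [models[d].best_score
                                     for d in weights.index])
    weights.insert(2, "ensemble_size", [models[d].ensemble_size
                                        for d in weights.index])
    paths = [_out(config, "donor_weights.csv"), _out(config, "run_log.json")]
    weights.to_csv(paths[0])
    with open(paths[1], "w") as fh:
        json.dump({"seed": config.seed, "params": asdict(params),
                   "donors": {d: {"best_score": m.best_score,
                                  "ensemble_size": m.ensemble_size}
                              for d, m in sorted(models.items())}},
                  fh, indent=1, sort_keys=True)
    return paths


def _load_models(config: PipelineConfig
                 ) -> tuple[dict[str, dict[str, DonorModel]], list[str]]:
    weights = pd.read_csv(_out(config, "donor_weights.csv"), index_col=0)
    edge_cols = [c for c in weights.columns
                 if c not in ("group", "best_score", "ensemble_size")]
    by_group: dict[str, dict[str, DonorModel]] = {}
    for donor, row in weights.iterrows():
        m = DonorModel(edge_weights=row[edge_cols].to_numpy(dtype=float),
                       best_score=float(row["best_score"]),
                       ensemble_size=int(row["ensemble_size"]))
        by_group.setdefault(row["group"], {})[donor] = m
    return by_group, edge_cols


def stage_merge(config: PipelineConfig) -> list[Path]:
    by_group, edge_ids = _load_models(config)
    nets = {g: merge_subgroup(list(models.values()), g, edge_ids)
            for g, models in by_group.items()}
    activity = pd.DataFrame({g: n.edge_activity for g, n in nets.items()},
                            index=edge_ids)
    active = pd.DataFrame({g: n.active_mask for g, n in nets.items()},
                          index=edge_ids).astype(int)
    report = distance_report(by_group, config.healthy_group,
                             hyperedge_ids=edge_ids)
    paths = [_out(config, n) for n in
             ("subgroup_activity.csv", "subgroup_active_mask.csv",
              "distance_report.csv", "distance_summary.csv")]
    activity.rename_axis("interaction").to_csv(paths[0])
    active.rename_axis("interaction").to_csv(paths[1])
    report.per_donor.to_csv(paths[2], index=False)
    pd.DataFrame({"median_distance": report.group_medians,
                  "rank_sum_p_vs_background": report.rank_sum_p}).to_csv(
        paths[3])
    return paths


def _subgroup_nets(config: PipelineConfig):
    by_group, edge_ids = _load_models(config)
    nets = {g: merge_subgroup(list(models.values()), g, edge_ids)
            for g, models in by_group.items()}
    return by_group, edge_ids, nets


def stage_codrug(config: PipelineConfig) -> list[Path]:
    by_group, edge_ids, nets = _subgroup_nets(config)
    healthy, untreated = config.healthy_group, config.untreated_group
    treatments = [g for g in nets if g not in (healthy, untreated)]
    wh = np.array([m.edge_weights
                   for m in by_group[healthy].values()])
    tables = []
    for t in sorted(treatments):
        wt = np.array([m.edge_weights for m in by_group[t].values()])
        tables.append(codruggability_table(
            nets[healthy], nets[untreated], nets[t], wh, wt,
            config.thresholds))
    path = _out(config, "codruggability.csv")
    pd.concat(tables, ignore_index=True).to_csv(path, index=False)
    return [path]


def stage_predict(config: PipelineConfig) -> list[Path]:
    _, edge_ids, nets = _subgroup_nets(config)
    pkn = _load_network(config)
    model = LogicModel(pkn)
    stimuli, readouts = _panel(config, pkn)
    records = pd.read_csv(_out(config, "codruggability.csv"))
    tables, flagged_tables = [], []
    for t, sub in records.groupby("treatment"):
        tables.append(predict_combinations(model, nets[t], sub,
                                           stimuli, readouts))
        flagged_tables.append(sub)
    predictions = (pd.concat(tables, ignore_index=True) if tables
                   else pd.DataFrame())
    summary = summarize_by_interaction(flagged_tables)
    paths = [_out(config, "predictions.csv"),
             _out(config, "interaction_summary.csv")]
    predictions.to_csv(paths[0], index=False)
    summary.to_csv(paths[1], index=False)
    return paths


def stage_confirm(config: PipelineConfig) -> list[Path]:
    _, edge_ids, nets = _subgroup_nets(config)
    pkn = _load_network(config)
    model = LogicModel(pkn)
    stimuli, readouts = _panel(config, pkn)
    table = pd.read_csv(_out(config, "normalized.csv"))
    groups = pd.read_csv(_out(config, "groups.csv"))
    group_of = dict(zip(groups["donor"], groups["group"]))
    confirmation = confirm_subgroups(
        table[["donor", "stimulus", "readout", "fc"]], group_of, model, nets,
        stimuli, readouts)
    paths = [_out(config, "confirmation_pairs.csv"),
             _out(config, "confirmation_enrichment.csv")]
    confirmation.pairs.to_csv(paths[0], index=False)
    confirmation.enrichment.to_csv(paths[1], index=False)
    return paths


STAGES = {
    "simulate": stage_simulate,
    "normalize": stage_normalize,
    "fit": stage_fit,
    "merge": stage_merge,
    "codrug": stage_codrug,
    "predict": stage_predict,
    "confirm": stage_confirm,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write a run manifest."""
    config.validate()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "normalization": asdict(config.normalization),
            "training": asdict(config.training),
            "thresholds": asdict(config.thresholds),
            "synthetic": (asdict(config.synthetic)
                          if config.synthetic else None),
        },
        "stages": {},
        "inputs": {},
    }
    for key in ("pkn_sif", "annotations", "and_gates", "midas"):
        path = getattr(config, key)
        if path is not None:
            manifest["inputs"][key] = {"path": str(path),
                                       "sha256": _sha256(Path(path))}
    for name, fn in STAGES.items():
        if name == "simulate" and config.synthetic is None:
            continue
        try:
            outputs = fn(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            str(p.name): _sha256(p) for p in outputs}
    path = _out(config, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
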