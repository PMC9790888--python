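"""Closed-loop campaign orchestration: propose → assay → select → fit → screen.

A campaign runs the generation loop against either the virtual lab or
externally supplied motility ledgers.  Each generation proposes a trial
population by differential evolution (oversampled and screened by the
surrogate from ``surrogate_start_generation`` onward), obtains straw-level
motility records, aggregates them to per-(formulation, bull) scores under
the scheduled metric (total motility early, relative total motility late),
and applies pooled elitist selection against the current parents.

Mid-campaign protocol events are first-class configuration: the optimization
metric switches by schedule, and components can be removed at a scheduled
generation (the column is kept, frozen at zero — the schema never changes).

Reproducibility contract: every generation derives its RNG deterministically
from ``(seed, generation)``, so re-running from any ledger prefix with the
same seed produces byte-identical subsequent ledgers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import equivstats, evolution, surrogate, virtual_lab
from .equivstats import EquivalenceConfig, build_score_table, generation_summary
from .evolution import DEConfig, Population
from .exceptions import ConfigError, DataError, IngestError, StateError
from .formulation_space import (
    Formulation,
    FormulationSpace,
    control_extender,
    default_space,
    formulations_to_frame,
    validate,
)
from .surrogate import SurrogateConfig, TrainingPair, featurize
from .virtual_lab import (
    NoiseModel,
    RECORD_COLUMNS,
    ResponseSurfaceParams,
    default_surface,
    records_to_frame,
    simulate_generation,
)

LEDGER_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class CampaignConfig:
    """Everything a campaign run needs, serializable to YAML."""

    seed: int = 0
    de: DEConfig = field(default_factory=DEConfig)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    equivalence: EquivalenceConfig = field(default_factory=EquivalenceConfig)
    #: generation -> metric; the metric of generation g is the entry with the
    #: largest key <= g (total motility early, relative from generation 18)
    metric_schedule: Mapping[int, str] = field(
        default_factory=lambda: {1: "total", 18: "relative"}
    )
    surrogate_start_generation: int = 7
    model_choice: str = "auto"  # auto | ann | gpr
    #: generation -> component names removed (frozen at 0) from that point on
    component_removals: Mapping[int, tuple[str, ...]] = field(
        default_factory=lambda: {19: ("ngf",)}
    )
    max_generations: int = 20
    stop_on_convergence: bool = True
    convergence_window: int = 3
    convergence_alpha: float = 0.05
    bulls_per_generation: int = 4
    replicates: int = 3
    score_aggregation: str = "median"  # per-formulation across bulls

    def metric_for(self, generation: int) -> str:
        keys = [g for g in self.metric_schedule if g <= generation]
        if not keys:
            raise ConfigError(f"no metric scheduled for generation {generation}")
        return self.metric_schedule[max(keys)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metric_schedule"] = {int(k): v for k, v in self.metric_schedule.items()}
        d["component_removals"] = {
            int(k): list(v) for k, v in self.component_removals.items()
        }
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CampaignConfig":
        d = dict(d)
        for key, sub in (
            ("de", DEConfig),
            ("surrogate", SurrogateConfig),
            ("equivalence", EquivalenceConfig),
        ):
            if key in d and isinstance(d[key], Mapping):
                d[key] = sub(**d[key])
        if "metric_schedule" in d:
            d["metric_schedule"] = {int(k): v for k, v in d["metric_schedule"].items()}
        if "component_removals" in d:
            d["component_removals"] = {
                int(k): tuple(v) for k, v in d["component_removals"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CampaignConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class VirtualLab:
    """Assay provider backed by the synthetic response surface."""

    def __init__(
        self,
        space: FormulationSpace,
        params: ResponseSurfaceParams | None = None,
        noise: NoiseModel | None = None,
    ):
        self.space = space
        self.params = params or default_surface()
        self.noise = noise or NoiseModel()

    def run_assay(
        self,
        formulations: Sequence[Formulation],
        generation: int,
        cfg: CampaignConfig,
        rng: np.random.Generator,
    ) -> pd.DataFrame:
        bulls = [f"bull_{generation}_{i}" for i in range(1, cfg.bulls_per_generation + 1)]
        records = simulate_generation(
            formulations,
            bulls,
            cfg.replicates,
            self.params,
            self.noise,
            self.space,
            rng,
            generation,
            control=control_extender(self.space),
        )
        return records_to_frame(records)


@dataclass
class CampaignState:
    """Mutable run state: current parents, ledgers and protocol bookkeeping."""

    space: FormulationSpace
    generation: int = 0
    parents: Population | None = None
    model_tag: str | None = None
    formulations: pd.DataFrame = field(default_factory=pd.DataFrame)
    motility: pd.DataFrame = field(default_factory=pd.DataFrame)
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: per-generation arrays of the metric values used for scoring
    generation_scores: dict[int, np.ndarray] = field(default_factory=dict)
    converged: bool = False
    log: list[str] = field(default_factory=list)

    def write_ledgers(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.formulations.to_csv(
            outdir / "formulations.csv", index=False, float_format=LEDGER_FLOAT_FORMAT
        )
        self.motility.to_csv(
            outdir / "motility.csv", index=False, float_format=LEDGER_FLOAT_FORMAT
        )
        self.predictions.to_csv(
            outdir / "predictions.csv", index=False, float_format=LEDGER_FLOAT_FORMAT
        )


def _generation_rng(seed: int, generation: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, generation, stream])


def _formulation_scores(
    table: pd.DataFrame, ids: Sequence[str], aggregation: str
) -> np.ndarray:
    agg = table.groupby("formulation_id")["score"].agg(aggregation)
    return np.array([float(agg[i]) for i in ids])


def _training_pairs(state: CampaignState, cfg: CampaignConfig) -> list[TrainingPair]:
    """All historical per-(formulation, bull) pairs on the total-motility scale.

    The surrogate always regresses total motility (a stable physical scale);
    the optimization metric only affects selection.
    """
    table = build_score_table(state.motility, metric="total")
    id_to_conc = {
        row["formulation_id"]: np.array(
            [row[name] for name in state.space.names], dtype=float
        )
        for _, row in state.formulations.iterrows()
    }
    pairs = []
    for _, row in table.iterrows():
        fid = row["formulation_id"]
        if fid not in id_to_conc:
            continue
        f = Formulation(fid, id_to_conc[fid])
        pairs.append(
            TrainingPair(featurize(f, state.space), float(row["total_motility"]))
        )
    return pairs


def _fit_surrogate(tag: str, pairs: Sequence[TrainingPair], cfg: SurrogateConfig):
    if tag == "ann":
        return surrogate.fit_ann(pairs, cfg)
    if tag == "gpr":
        return surrogate.fit_gpr(pairs, cfg)
    raise ConfigError(f"unknown surrogate model {tag!r}")


def _select_model(state: CampaignState, cfg: CampaignConfig) -> str:
    """One-shot model selection: train on all but the latest generation,
    predict the latest, compare predictions with the experimental sample."""
    holdout_gen = state.generation
    train_pairs, holdout = [], []
    table = build_score_table(state.motility, metric="total")
    id_to_conc = {
        row["formulation_id"]: np.array(
            [row[name] for name in state.space.names], dtype=float
        )
        for _, row in state.formulations.iterrows()
    }
    for _, row in table.iterrows():
        f = Formulation(row["formulation_id"], id_to_conc[row["formulation_id"]])
        pair = TrainingPair(featurize(f, state.space), float(row["total_motility"]))
        (holdout if row["generation"] == holdout_gen else train_pairs).append(pair)
    if len(train_pairs) < cfg.surrogate.cv_folds or len(holdout) < 2:
        return "gpr"  # not enough history to run the comparison
    X_hold = np.stack([p.features for p in holdout])
    y_hold = np.array([p.target for p in holdout])
    ann = _fit_surrogate("ann", train_pairs, cfg.surrogate)
    gpr = _fit_surrogate("gpr", train_pairs, cfg.surrogate)
    report = surrogate.compare_models(
        ann.predict(X_hold), gpr.predict(X_hold), y_hold,
        alpha=cfg.convergence_alpha, equivalence_cfg=cfg.equivalence,
    )
    state.log.append(
        f"model selection at generation {holdout_gen}: picked {report.selected} "
        f"({report.rule})"
    )
    return report.selected


def _convergence_window_ready(g: int, cfg: CampaignConfig) -> bool:
    """Whether the plateau test is meaningful at generation ``g``.

    The omnibus test compares score distributions across generations, which
    is only interpretable when the window shares one metric — and, when the
    schedule contains a relative-motility era, only within that era: under
    raw total motility each generation's bull panel shifts its whole score
    distribution, confounding the between-generation comparison the plateau
    test relies on.  The relative metric cancels the shared bull effect.
    """
    window = range(g - cfg.convergence_window + 1, g + 1)
    if window[0] < 1:
        return False
    metrics = {cfg.metric_for(i) for i in window}
    if len(metrics) > 1:
        return False
    if "relative" in set(cfg.metric_schedule.values()):
        return metrics == {"relative"}
    return True


def run_generation(
    state: CampaignState,
    cfg: CampaignConfig,
    lab: VirtualLab | None = None,
    records: pd.DataFrame | None = None,
) -> CampaignState:
    """Advance the campaign by one generation (in place; returns the state).

    In virtual mode ``lab`` supplies the assay; in external mode pre-validated
    ``records`` for the proposed formulations must be passed instead.
    """
    g = state.generation + 1
    if g > 1 and state.parents is None:
        raise StateError("state has no parents; run generation 1 first")
    rng = _generation_rng(cfg.seed, g)

    removed = cfg.component_removals.get(g, ())
    if removed:
        state.space = state.space.with_deactivated(removed)
        if state.parents is not None:
            for m in state.parents.members:
                for name in removed:
                    m.concentrations[state.space.index(name)] = 0.0
        state.log.append(f"generation {g}: removed components {list(removed)}")

    k = cfg.de.population_size
    surrogate_active = g >= cfg.surrogate_start_generation and cfg.model_choice != "off"
    if g == 1:
        trials = evolution.init_population(state.space, cfg.de, rng)
    else:
        n_trials = k * (cfg.de.candidate_oversampling if surrogate_active else 1)
        trials = evolution.mutate_rand_1_bin(
            state.parents, cfg.de, state.space, rng, g, n_trials=n_trials
        )

    if surrogate_active and g > 1:
        if state.model_tag is None:
            state.model_tag = (
                _select_model(state, cfg) if cfg.model_choice == "auto"
                else cfg.model_choice
            )
        pairs = _training_pairs(state, cfg)[-cfg.surrogate.max_training_pairs :]
        model = _fit_surrogate(state.model_tag, pairs, cfg.surrogate)
        trials, preds = surrogate.screen_candidates(model, trials, k, state.space)
        pred_sd = (
            model.predict_sd(surrogate.featurize_population(trials.members, state.space))
            if hasattr(model, "predict_sd")
            else np.full(len(trials), np.nan)
        )
        kept_pred = np.asarray(
            model.predict(surrogate.featurize_population(trials.members, state.space))
        )
        pred_frame = pd.DataFrame(
            {
                "generation": g,
                "formulation_id": [m.id for m in trials.members],
                "model_tag": state.model_tag,
                "predicted_motility": kept_pred,
                "predicted_sd": pred_sd,
            }
        )
        state.predictions = pd.concat(
            [state.predictions, pred_frame], ignore_index=True
        )

    for m in trials.members:
        violations = validate(m, state.space)
        if violations:  # pragma: no cover - clip_to_bounds guarantees validity
            raise StateError(f"proposed formulation invalid: {violations}")

    if records is None:
        if lab is None:
            raise ConfigError("virtual mode needs a lab; external mode needs records")
        assay_rng = _generation_rng(cfg.seed, g, stream=1)
        records = lab.run_assay(trials.members, g, cfg, assay_rng)
    else:
        records = ingest_external(records, [m.id for m in trials.members])

    metric = cfg.metric_for(g)
    table = build_score_table(records, metric=metric)
    trial_ids = [m.id for m in trials.members]
    trials.scores = _formulation_scores(table, trial_ids, cfg.score_aggregation)

    if g == 1 or state.parents is None:
        state.parents = trials
    else:
        parent_metric_stale = cfg.metric_for(g - 1) != metric
        if parent_metric_stale:
            # re-derive parent scores under the new metric from their own assays
            hist = build_score_table(state.motility, metric=metric)
            pid = [m.id for m in state.parents.members]
            state.parents.scores = _formulation_scores(
                hist, pid, cfg.score_aggregation
            )
        if cfg.de.selection == "pairwise" and len(trials) == len(state.parents):
            state.parents = evolution.select_pairwise(state.parents, trials)
        else:
            state.parents = evolution.select_top(state.parents, trials, k)

    state.formulations = pd.concat(
        [state.formulations, formulations_to_frame(trials.members, state.space, g)],
        ignore_index=True,
    )
    state.motility = pd.concat([state.motility, records], ignore_index=True)
    state.generation_scores[g] = np.asarray(table["score"], dtype=float)
    state.generation = g

    if cfg.stop_on_convergence and _convergence_window_ready(g, cfg):
        recent = [
            state.generation_scores[i]
            for i in range(g - cfg.convergence_window + 1, g + 1)
        ]
        state.converged = evolution.check_convergence(recent, cfg.convergence_alpha)
        if state.converged:
            state.log.append(f"converged at generation {g} (score plateau)")
    return state


def run_campaign(
    cfg: CampaignConfig,
    lab: VirtualLab | None = None,
    space: FormulationSpace | None = None,
    state: CampaignState | None = None,
) -> CampaignState:
    """Run generations until convergence or the generation cap.

    Pass an existing ``state`` to resume; resuming reproduces exactly what an
    uninterrupted run would have produced (per-generation RNG streams).
    """
    space = space or default_space()
    lab = lab or VirtualLab(space)
    state = state or CampaignState(space=space)
    while state.generation < cfg.max_generations and not state.converged:
        run_generation(state, cfg, lab=lab)
    return state


def ingest_external(records: pd.DataFrame, proposed_ids: Sequence[str]) -> pd.DataFrame:
    """Validate an externally measured motility ledger against the schema.

    Checks columns, motility ranges (rows reported by number), coverage of
    every proposed formulation, and control presence per (generation, bull).
    """
    missing_cols = set(RECORD_COLUMNS) - set(records.columns)
    if missing_cols:
        raise IngestError(f"missing columns: {sorted(missing_cols)}")
    if records["control_motility"].isna().any():
        bulls = sorted(
            records.loc[records["control_motility"].isna(), "bull_id"].unique()
        )
        raise IngestError(f"missing control rows for bulls {bulls}")
    bad_rows = [
        int(i)
        for i, row in records.iterrows()
        if not (0 <= row["total_motility"] <= 100)
        or not (0 <= row["control_motility"] <= 100)
    ]
    if bad_rows:
        raise IngestError(f"motility outside [0, 100] in rows {bad_rows}")
    covered = set(records["formulation_id"])
    absent = [i for i in proposed_ids if i not in covered]
    if absent:
        raise IngestError(f"no motility records for proposed formulations {absent}")
    return records[RECORD_COLUMNS].copy()


def rank_top_media(
    motility: pd.DataFrame, k: int = 5
) -> tuple[pd.DataFrame, dict]:
    """Rank formulations by mean relative total motility across their bulls.

    Returns the top-k table (per-formulation mean total/control motility and
    percent improvement) and a pooled summary across the selected media.
    Asks for more media than exist? The full pool is returned (flagged).
    """
    table = build_score_table(motility, metric="relative")
    per_form = (
        table.groupby("formulation_id")
        .agg(
            mean_relative=("relative_total_motility", "mean"),
            mean_total=("total_motility", "mean"),
            mean_control=("control_motility", "mean"),
            n_bulls=("bull_id", "nunique"),
            generation=("generation", "max"),
        )
        .reset_index()
        .sort_values(["mean_relative", "formulation_id"], ascending=[False, True])
    )
    truncated = k > len(per_form)
    top = per_form.head(min(k, len(per_form))).copy()
    top["percent_improvement"] = 100.0 * (top["mean_total"] / top["mean_control"] - 1.0)
    mean_t = float(top["mean_total"].mean())
    mean_c = float(top["mean_control"].mean())
    summary = {
        "k": int(len(top)),
        "requested_k": k,
        "pool_exhausted": truncated,
        "mean_total_motility": mean_t,
        "mean_control_motility": mean_c,
        "percent_improvement": equivstats.percent_improvement(mean_t, mean_c),
    }
    return top.reset_index(drop=True), summary


def final_report(state: CampaignState, cfg: CampaignConfig) -> dict:
    """Trajectory table, top-5 media and final-generation control comparison."""
    frames = []
    for g in sorted(state.motility["generation"].unique()):
        sub = state.motility[state.motility["generation"] == g]
        frames.append(generation_summary(sub, metric=cfg.metric_for(int(g))))
    trajectory = pd.concat(frames, ignore_index=True)
    top, top_summary = rank_top_media(state.motility, k=5)
    last = state.motility[state.motility["generation"] == state.generation]
    control_comparison = None
    if len(last) > 0:
        treatment = build_score_table(last, metric="total")["total_motility"]
        control = (
            last.groupby("bull_id")["control_motility"].mean().to_numpy()
        )
        if len(control) >= 2 and len(treatment) >= 2:
            try:
                control_comparison = equivstats.mann_whitney_equivalence(
                    treatment.to_numpy(), control, cfg.equivalence
                )
            except DataError:  # degenerate (e.g. completely separated) samples
                control_comparison = None
    return {
        "generations_run": state.generation,
        "converged": state.converged,
        "model_tag": state.model_tag,
        "trajectory": trajectory,
        "top_media": top,
        "top_summary": top_summary,
        "control_comparison": control_comparison,
        "log": list(state.log),
    }


def state_to_json(state: CampaignState) -> str:
    """Serialize the resumable part of the state (ledgers live in CSVs)."""
    payload = {
        "generation": state.generation,
        "model_tag": state.model_tag,
        "converged": state.converged,
        "inactive": [n for n, a in zip(state.space.names, state.space.active) if not a],
        "parents": None,
        "log": state.log,
        "generation_scores": {
            str(g): list(map(float, v)) for g, v in state.generation_scores.items()
        },
    }
    if state.parents is not None:
        payload["parents"] = {
            "generation": state.parents.generation,
            "ids": [m.id for m in state.parents.members],
            "provenance": [m.provenance for m in state.parents.members],
            "concentrations": [
                list(map(float, m.concentrations)) for m in state.parents.members
            ],
            "scores": (
                list(map(float, state.parents.scores))
                if state.parents.scores is not None
                else None
            ),
        }
    return json.dumps(payload, indent=1)


def state_from_json(
    text: str,
    space: FormulationSpace,
    formulations: pd.DataFrame,
    motility: pd.DataFrame,
    predictions: pd.DataFrame,
) -> CampaignState:
    payload = json.loads(text)
    if payload["inactive"]:
        space = space.with_deactivated(payload["inactive"])
    parents = None
    if payload["parents"] is not None:
        p = payload["parents"]
        parents = Population(
            generation=p["generation"],
            members=[
                Formulation(i, np.array(c), prov)
                for i, c, prov in zip(p["ids"], p["concentrations"], p["provenance"])
            ],
            scores=np.array(p["scores"]) if p["scores"] is not None else None,
        )
    return CampaignState(
        space=space,
        generation=payload["generation"],
        parents=parents,
        model_tag=payload["model_tag"],
        formulations=formulations,
        motility=motility,
        predictions=predictions,
        generation_scores={
            int(g): np.array(v) for g, v in payload["generation_scores"].items()
        },
        converged=payload["converged"],
        log=list(payload["log"]),
    )
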