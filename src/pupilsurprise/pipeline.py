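"""Pipeline driver: simulate -> infer priors -> update -> surprise -> analyze.

Per child, the modelling stages are:

1. *Priors* — the pretest-inferred belief state (product of response
   likelihoods over the pretest trials from a uniform start).
2. *Trajectories* — sequential Bayesian updating of that prior against the
   learning-phase outcomes.
3. *Surprise* — per-trial Shannon information, KL divergence, and JS
   divergence along the trajectory, plus min-max normalized columns for
   cross-metric regime comparisons.

The analysis stage pools trials within condition for the Condition x
Estimate correlation grid across four scopes (all, learners,
already-knowers, critical trials) and computes the cross-child
correlation-of-correlations.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    SCOPES,
    AnalysisGrid,
    condition_analysis,
    individual_differences,
    subset_learners,
)
from .belief import BeliefState, convergence_trial, trajectory_array
from .config import PipelineConfig
from .io import (
    Dataset,
    cohort_to_dataset,
    read_tables,
    trials_from_frame,
    write_dataset,
    write_table,
)
from .stimuli import (
    Phase,
    Rule,
    Trial,
    outcome_likelihood_vector,
    response_likelihood_matrix,
)
from .surprise import minmax_normalize, surprise_series_arrays
from .synthetic import Cohort, generate_cohort

__all__ = [
    "ModeledChild",
    "ModeledData",
    "RunManifest",
    "PipelineStageError",
    "model_cohort",
    "model_dataset",
    "run_pipeline",
    "report",
]

log = logging.getLogger("pupilsurprise")

BELIEF_COLUMNS = ["w_size", "w_material", "w_mass", "w_random"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a repro hint."""

    def __init__(self, stage: str, seed: int, cause: Exception):
        super().__init__(
            f"stage '{stage}' failed: {cause} "
            f"(reproduce with: pupilsurprise run --seed {seed})"
        )
        self.stage = stage


@dataclass
class ModeledChild:
    child_id: str
    condition: str
    prior: BeliefState  # pretest-inferred
    states: np.ndarray  # (T+1, 4)
    si: np.ndarray
    kld: np.ndarray
    jsd: np.ndarray
    responses: np.ndarray  # learning-phase 5-point responses
    expected: np.ndarray  # model-expected responses, pre-update states
    pupil: np.ndarray | None
    convergence: int | None
    trial_index: np.ndarray


@dataclass
class ModeledData:
    children: dict[str, ModeledChild]
    partition: dict[str, list[str]]
    beliefs: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    surprise: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    merged: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    convergence: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def has_pupil(self) -> bool:
        return any(c.pupil is not None for c in self.children.values())

    def per_child_series(self) -> dict[str, dict[str, np.ndarray]]:
        """Series bundle consumed by the individual-differences analysis."""
        out = {}
        for cid, child in self.children.items():
            if child.pupil is None:
                continue
            out[cid] = {
                "responses": child.responses,
                "expected": child.expected,
                "pupil": child.pupil,
                "kld": child.kld,
                "si": child.si,
            }
        return out


def _model_child(
    child_id: str,
    condition: str,
    pretest_trials: list[Trial],
    pretest_responses: np.ndarray,
    learning_trials: list[Trial],
    learning_responses: np.ndarray,
    pupil: np.ndarray | None,
    pre_resp_tables: np.ndarray,  # (P, 4, 5)
    learn_lik: np.ndarray,  # (T, 4)
    learn_expected_per_rule: np.ndarray,  # (T, 4)
    epsilon: float,
    eta: float,
    log_base: float,
    odds_threshold: float,
) -> ModeledChild:
    P = len(pretest_trials)
    weights = np.full(4, 0.25)
    if P:
        picks = pre_resp_tables[np.arange(P), :, pretest_responses - 1]  # (P, 4)
        weights = weights * picks.prod(axis=0)
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            f"child {child_id}: pretest responses have zero likelihood under "
            "every rule (degenerate prior)"
        )
    prior = BeliefState(weights / total)
    states = trajectory_array(prior.weights, learn_lik)
    si, kld, jsd = surprise_series_arrays(prior.weights, learn_lik, log_base)
    expected = np.einsum("tj,tj->t", states[:-1], learn_expected_per_rule)
    return ModeledChild(
        child_id=child_id,
        condition=condition,
        prior=prior,
        states=states,
        si=si,
        kld=kld,
        jsd=jsd,
        responses=learning_responses.astype(float),
        expected=expected,
        pupil=pupil,
        convergence=convergence_trial(states, Rule.SIZE, odds_threshold),
        trial_index=np.array([t.trial_index for t in learning_trials]),
    )


def _assemble(children: dict[str, ModeledChild], norm_scope: str) -> ModeledData:
    partition = subset_learners({cid: c.prior for cid, c in children.items()})
    knowers = set(partition["already_knowers"])

    belief_rows, surprise_rows, merged_rows, conv_rows = [], [], [], []
    for cid, c in children.items():
        for t, row in enumerate(c.states):
            belief_rows.append({"child_id": cid, "t": t,
                                **dict(zip(BELIEF_COLUMNS, row))})
        for i, ti in enumerate(c.trial_index):
            surprise_rows.append(
                {"child_id": cid, "trial_index": int(ti),
                 "si": c.si[i], "kld": c.kld[i], "jsd": c.jsd[i]}
            )
            merged_rows.append(
                {
                    "child_id": cid,
                    "condition": c.condition,
                    "trial_index": int(ti),
                    "si": c.si[i],
                    "kld": c.kld[i],
                    "jsd": c.jsd[i],
                    "response": c.responses[i],
                    "expected_response": c.expected[i],
                    "pupil_change": c.pupil[i] if c.pupil is not None else np.nan,
                    "already_knower": cid in knowers,
                }
            )
        conv_rows.append(
            {"child_id": cid, "condition": c.condition,
             "already_knower": cid in knowers,
             "convergence_trial": c.convergence if c.convergence is not None else -1}
        )

    surprise_df = pd.DataFrame(surprise_rows)
    merged = pd.DataFrame(merged_rows)

    # normalized columns for cross-metric comparison (0-1 within scope)
    cond_of = {cid: c.condition for cid, c in children.items()}
    for col in ("si", "kld"):
        norm = np.full(len(surprise_df), np.nan)
        if norm_scope == "pooled":
            groups = [np.ones(len(surprise_df), dtype=bool)]
        elif norm_scope == "child":
            groups = [
                (surprise_df["child_id"] == cid).to_numpy() for cid in children
            ]
        else:  # condition
            conds = surprise_df["child_id"].map(cond_of)
            groups = [(conds == c).to_numpy() for c in sorted(set(cond_of.values()))]
        for mask in groups:
            if mask.any():
                norm[mask] = minmax_normalize(surprise_df.loc[mask, col].to_numpy())
        surprise_df[f"{col}_norm"] = norm

    return ModeledData(
        children=children,
        partition=partition,
        beliefs=pd.DataFrame(belief_rows),
        surprise=surprise_df,
        merged=merged,
        convergence=pd.DataFrame(conv_rows),
    )


def model_cohort(
    cohort: Cohort,
    epsilon: float | None = None,
    eta: float | None = None,
    log_base: float = math.e,
    odds_threshold: float = 10.0,
    norm_scope: str = "condition",
) -> ModeledData:
    """Fast modelling path for a simulated cohort (shared trial sequence)."""
    epsilon = cohort.config.epsilon if epsilon is None else epsilon
    eta = cohort.config.eta if eta is None else eta
    pretest, learning = cohort.pretest_trials, cohort.learning_trials

    pre_resp_tables = np.array(
        [response_likelihood_matrix(t, eta) for t in pretest]
    ).reshape(len(pretest), 4, 5)
    learn_lik = np.array(
        [outcome_likelihood_vector(t, t.outcome, epsilon) for t in learning]
    ).reshape(len(learning), 4)
    learn_expected = np.array(
        [response_likelihood_matrix(t, eta) @ np.arange(1, 6) for t in learning]
    ).reshape(len(learning), 4)

    resp = cohort.responses
    pre_wide = (
        resp[resp["phase"] == "pretest"]
        .pivot(index="child_id", columns="trial_index", values="response")
    )
    learn_wide = (
        resp[resp["phase"] == "learning"]
        .pivot(index="child_id", columns="trial_index", values="response")
    )
    pupil_wide = cohort.pupil.pivot(
        index="child_id", columns="trial_index", values="pupil_change"
    )

    children: dict[str, ModeledChild] = {}
    for row in cohort.children.itertuples():
        cid = row.child_id
        children[cid] = _model_child(
            child_id=cid,
            condition=row.condition,
            pretest_trials=pretest,
            pretest_responses=pre_wide.loc[cid].to_numpy(dtype=int)
            if len(pretest) else np.empty(0, dtype=int),
            learning_trials=learning,
            learning_responses=learn_wide.loc[cid].to_numpy(dtype=int),
            pupil=pupil_wide.loc[cid].to_numpy(dtype=float),
            pre_resp_tables=pre_resp_tables,
            learn_lik=learn_lik,
            learn_expected_per_rule=learn_expected,
            epsilon=epsilon,
            eta=eta,
            log_base=log_base,
            odds_threshold=odds_threshold,
        )
    return _assemble(children, norm_scope)


def _child_param(row, name: str, default: float) -> float:
    """Per-child noise parameter from the children table, if present."""
    value = getattr(row, name, None)
    try:
        value = float(value)
    except (TypeError, ValueError):
        return default
    return value if np.isfinite(value) else default


def model_dataset(
    dataset: Dataset,
    epsilon: float = 0.1,
    eta: float = 0.1,
    log_base: float = math.e,
    odds_threshold: float = 10.0,
    norm_scope: str = "condition",
) -> ModeledData:
    """General modelling path over validated dataset tables (per-child trials)."""
    trials_by_child = dict(tuple(dataset.trials.groupby("child_id", sort=False)))
    resp = dataset.responses
    pupil = dataset.pupil

    children: dict[str, ModeledChild] = {}
    for row in dataset.children.itertuples():
        cid = row.child_id
        block = trials_by_child.get(cid)
        if block is None:
            raise ValueError(f"no trials found for child {cid!r}")
        trials = trials_from_frame(block)
        pretest = [t for t in trials if t.phase is Phase.PRETEST]
        learning = sorted(
            (t for t in trials if t.phase is Phase.LEARNING),
            key=lambda t: t.trial_index,
        )
        child_eps = _child_param(row, "epsilon", epsilon)
        child_eta = _child_param(row, "eta", eta)

        sub = resp[resp["child_id"] == cid]
        pre_map = dict(
            zip(sub[sub["phase"] == "pretest"]["trial_index"].astype(int),
                sub[sub["phase"] == "pretest"]["response"].astype(int))
        )
        learn_map = dict(
            zip(sub[sub["phase"] == "learning"]["trial_index"].astype(int),
                sub[sub["phase"] == "learning"]["response"].astype(int))
        )
        missing = [t.trial_index for t in learning if t.trial_index not in learn_map]
        if missing:
            raise ValueError(
                f"child {cid!r}: missing learning responses for trials {missing[:5]}"
            )
        pupil_arr = None
        if pupil is not None:
            psub = pupil[pupil["child_id"] == cid]
            pmap = dict(zip(psub["trial_index"].astype(int),
                            psub["pupil_change"].astype(float)))
            if pmap:
                absent = [t.trial_index for t in learning if t.trial_index not in pmap]
                if absent:
                    raise ValueError(
                        f"child {cid!r}: missing pupil values for trials {absent[:5]}"
                    )
                pupil_arr = np.array([pmap[t.trial_index] for t in learning])

        children[cid] = _model_child(
            child_id=cid,
            condition=str(row.condition),
            pretest_trials=pretest,
            pretest_responses=np.array(
                [pre_map[t.trial_index] for t in pretest], dtype=int
            ),
            learning_trials=learning,
            learning_responses=np.array(
                [learn_map[t.trial_index] for t in learning], dtype=int
            ),
            pupil=pupil_arr,
            pre_resp_tables=np.array(
                [response_likelihood_matrix(t, child_eta) for t in pretest]
            ).reshape(len(pretest), 4, 5),
            learn_lik=np.array(
                [outcome_likelihood_vector(t, t.outcome, child_eps) for t in learning]
            ).reshape(len(learning), 4),
            learn_expected_per_rule=np.array(
                [response_likelihood_matrix(t, child_eta) @ np.arange(1, 6)
                 for t in learning]
            ).reshape(len(learning), 4),
            epsilon=child_eps,
            eta=child_eta,
            log_base=log_base,
            odds_threshold=odds_threshold,
        )
    return _assemble(children, norm_scope)


def analysis_tables(
    modeled: ModeledData, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None, dict[str, AnalysisGrid]]:
    """Grids for all scopes + comparisons + individual differences as tables."""
    grid_rows, comp_rows = [], []
    grids: dict[str, AnalysisGrid] = {}
    for scope in SCOPES:
        grid = condition_analysis(
            modeled.merged.dropna(subset=["pupil_change"]),
            scope=scope,
            alpha=config.analysis.alpha,
            critical_window=tuple(config.analysis.critical_window),
            cell_sided=config.analysis.cell_sided,
            comparison_sided=config.analysis.comparison_sided,
        )
        grids[scope] = grid
        for (condition, estimate), cell in grid.cells.items():
            if cell is None:
                grid_rows.append(
                    {"scope": scope, "condition": condition, "estimate": estimate,
                     "r": np.nan, "n": 0, "df": 0, "p": np.nan,
                     "significant_at_corrected_alpha": False}
                )
            else:
                grid_rows.append(
                    {"scope": scope, "condition": condition, "estimate": estimate,
                     "r": cell.r, "n": cell.n, "df": cell.df, "p": cell.p,
                     "significant_at_corrected_alpha": cell.p < grid.alpha_corrected}
                )
        for comp in grid.comparisons:
            comp_rows.append(
                {"scope": scope, "method": comp.method, "contrast": comp.contrast,
                 "z": comp.z, "p": comp.p}
            )

    id_df = None
    per_child = modeled.per_child_series()
    if len(per_child) >= 3:
        result = individual_differences(per_child)
        id_df = pd.DataFrame(
            [
                {"metric": metric,
                 "r": result[metric].r, "n": result[metric].n,
                 "df": result[metric].df, "p": result[metric].p,
                 "n_excluded": result["n_excluded"]}
                for metric in ("kld", "si")
            ]
        )
    return pd.DataFrame(grid_rows), pd.DataFrame(comp_rows), id_df, grids


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, version, seed, checksums."""

    config: dict
    version: str
    seed: int
    output_dir: str
    checksums: dict[str, str]
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    def write(self, path: Path | str) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def read(cls, path: Path | str) -> "RunManifest":
        return cls.from_json(Path(path).read_text())


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig | None = None) -> RunManifest:
    """Execute the full pipeline and write all output tables plus a manifest.

    With no input directory configured, a synthetic cohort is generated at
    the configured seed; otherwise the existing tables are read and the
    simulation stage is skipped.
    """
    config = config or PipelineConfig()
    out_dir = Path(config.paths.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def stage(name: str):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineStageError(name, config.seed, exc) from exc
        return wrap

    # --- data stage -------------------------------------------------------
    if config.paths.input_dir:
        log.info("reading tables from %s (simulation skipped)", config.paths.input_dir)
        dataset = stage("read")(read_tables, config.paths.input_dir)
        if dataset.pupil is None:
            log.warning(
                "pupil table missing: analysis restricted to model/behaviour outputs"
            )
        modeled = stage("model")(
            model_dataset,
            dataset,
            epsilon=config.epsilon,
            eta=config.eta,
            log_base=config.log_base,
            odds_threshold=config.analysis.odds_threshold,
            norm_scope=config.analysis.norm_scope,
        )
    else:
        cohort_cfg = config.cohort.model_copy(
            update={"seed": config.seed, "epsilon": config.epsilon, "eta": config.eta}
        )
        log.info("simulating cohort of %d children (seed %d)",
                 cohort_cfg.n_children, config.seed)
        cohort = stage("simulate")(generate_cohort, cohort_cfg, config.pupil_model)
        dataset = cohort_to_dataset(cohort)
        for name, path in write_dataset(dataset, out_dir).items():
            written.append(path)
        modeled = stage("model")(
            model_cohort,
            cohort,
            log_base=config.log_base,
            odds_threshold=config.analysis.odds_threshold,
            norm_scope=config.analysis.norm_scope,
        )
    log.info("modelled %d children, %d learning trials each",
             len(modeled.children),
             len(next(iter(modeled.children.values())).trial_index))
    log.info("partition: %d learners, %d already-knowers",
             len(modeled.partition["learners"]),
             len(modeled.partition["already_knowers"]))

    written.append(write_table(modeled.beliefs, out_dir / "beliefs.csv", "beliefs"))
    written.append(write_table(modeled.surprise, out_dir / "surprise.csv", "surprise"))
    written.append(
        write_table(modeled.convergence, out_dir / "convergence.csv", "convergence")
    )

    # --- analysis stage ---------------------------------------------------
    if modeled.has_pupil:
        grid_df, comp_df, id_df, _ = stage("analyze")(analysis_tables, modeled, config)
        written.append(write_table(grid_df, out_dir / "results_grid.csv", "results_grid"))
        written.append(write_table(comp_df, out_dir / "comparisons.csv", "comparisons"))
        if id_df is not None:
            written.append(
                write_table(id_df, out_dir / "individual_differences.csv",
                            "individual_differences")
            )
    else:
        log.warning("no pupil data: correlation grids skipped")

    manifest = RunManifest(
        config=config.model_dump(mode="json"),
        version=__version__,
        seed=config.seed,
        output_dir=str(out_dir),
        checksums={p.name: _checksum(p) for p in written},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


def report(manifest: RunManifest | Path | str) -> str:
    """Human-readable summary of a completed run, rebuilt from its tables.

    Deterministic given the tables (timestamps excluded), so regenerating
    the report from the manifest reproduces it byte-for-byte.
    """
    if not isinstance(manifest, RunManifest):
        manifest = RunManifest.read(manifest)
    out_dir = Path(manifest.output_dir)
    lines = [
        f"pupilsurprise v{manifest.version} — seed {manifest.seed}",
        "",
    ]

    alpha = manifest.config["analysis"]["alpha"]
    corrected = alpha / manifest.config["analysis"]["family_size"]
    grid_path = out_dir / "results_grid.csv"
    if grid_path.exists():
        grid = pd.read_csv(grid_path, comment="#")
        for scope in SCOPES:
            sub = grid[grid["scope"] == scope]
            if sub.empty:
                continue
            lines.append(f"Scope: {scope}  (corrected alpha = {corrected:g})")
            lines.append("  condition     estimate   r          n        p        ")
            for row in sub.itertuples():
                if row.n == 0 or pd.isna(row.r):
                    lines.append(f"  {row.condition:<13} {row.estimate:<10} n/a")
                    continue
                flag = "*" if row.significant_at_corrected_alpha else " "
                lines.append(
                    f"  {row.condition:<13} {row.estimate:<10} "
                    f"{row.r:+.4f}    {row.n:<8d} {row.p:.4g} {flag}"
                )
            lines.append("")
    comp_path = out_dir / "comparisons.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path, comment="#")
        lines.append("Correlation comparisons:")
        for row in comp.itertuples():
            lines.append(
                f"  [{row.scope}] {row.contrast} ({row.method}): "
                f"z = {row.z:.3f}, p = {row.p:.4g}"
            )
        lines.append("")
    conv_path = out_dir / "convergence.csv"
    if conv_path.exists():
        conv = pd.read_csv(conv_path, comment="#")
        done = conv[conv["convergence_trial"] >= 1]
        lines.append(
            f"Convergence onto Size (posterior odds >= "
            f"{manifest.config['analysis']['odds_threshold']:g}): "
            f"{len(done)}/{len(conv)} children"
        )
        if len(done):
            lines.append(
                f"  median convergence trial: "
                f"{done['convergence_trial'].median():.1f}; "
                f"converged by trial 19: "
                f"{(done['convergence_trial'] <= 19).sum()}/{len(conv)}"
            )
        lines.append("")
    id_path = out_dir / "individual_differences.csv"
    if id_path.exists():
        iddf = pd.read_csv(id_path, comment="#")
        lines.append("Individual differences (cross-child correlation of fits):")
        for row in iddf.itertuples():
            lines.append(
                f"  pupil~{row.metric} fit vs behaviour fit: "
                f"r({row.df}) = {row.r:+.3f}, p = {row.p:.4g}  [n = {row.n}]"
            )
        lines.append("")
    return "\n".join(lines)
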