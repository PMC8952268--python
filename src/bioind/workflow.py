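"""End-to-end two-step workflow: HRT bioindicators, then performance prediction.

Step 1 trains an HRT8/HRT2 random-forest classifier per reactor on the
labeled sampling intervals (0-50 d and 141-211 d), runs recursive Gini
elimination and selects the A-/B-HRT bioindicator sets; the shared set is
their intersection.  Step 2 discovers non-HRT bioindicators per process
parameter, gates parameters on >80% out-of-bag explained variance in both
training orientations (for both set types), forms the time-independent set,
and evaluates the surviving parameters with the replicate-subsampled RRMSE
protocol on held-out reactors, for labeled samples and for all-phase
controls.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import prediction as pred
from . import selection as sel
from .diversity import observed_asvs
from .tables import AbundanceTable, SampleMetadata, assign_interval_and_label, to_relative

logger = logging.getLogger(__name__)

#: Default process parameters offered for quantitative prediction.
DEFAULT_PARAMETERS: tuple[str, ...] = (
    "conc_lactate", "conc_C4", "conc_C6", "conc_C8",
    "prod_C4", "prod_C6", "prod_C8",
    "yield_C4", "yield_C6", "yield_C8",
    "observed_asvs",
)


@dataclass
class WorkflowConfig:
    """Knobs of the two-step workflow.

    ``n_trees`` applies to every forest (the classifier, the elimination
    rounds, the regressors); 2000 matches the reference protocol, smaller
    values trade importance-ranking stability for speed on simulated data.
    """

    n_trees: int = 2000
    n_trees_regression: int | None = None  # None -> n_trees
    m_try_classifier: int = 40
    threshold_share: float = 0.01
    top_k: int = 15
    variance_gate: float = 80.0     # percent explained variance required
    rrmse_cutoff: float = 10.0      # percent, declares a parameter predictable
    n_replicates: int = 100
    subsample_hrt: int = 4
    subsample_nonhrt: int = 5
    parameters: tuple[str, ...] = DEFAULT_PARAMETERS
    #: parameters given the full replicate evaluation (the target products)
    eval_parameters: tuple[str, ...] = ("prod_C6", "prod_C8")
    seed: int = 0


@dataclass
class WorkflowResult:
    hrt_sets: dict[str, sel.BioindicatorSet]          # per training reactor
    shared: sel.BioindicatorSet
    cross_accuracy: dict[str, float]                  # "A->B" style keys
    oob_errors: dict[str, float]
    nonhrt_sets: dict[tuple[str, str], sel.BioindicatorSet]   # (parameter, reactor)
    gate_table: pd.DataFrame                          # explained variances
    passing_parameters: list[str]
    time_independent_per_parameter: dict[str, sel.BioindicatorSet]
    time_independent: sel.BioindicatorSet             # consensus across targets
    replicate_reports: list[pred.ReplicateResult] = field(default_factory=list)
    prediction_reports: list[pred.PredictionReport] = field(default_factory=list)

    def summary(self) -> dict:
        by_set: dict[str, list[float]] = {}
        for rep in self.replicate_reports:
            by_set.setdefault(rep.set_name.split("/")[0], []).append(rep.mean_rrmse)
        return {
            "shared_bioindicators": self.shared.asv_ids,
            "time_independent": self.time_independent.asv_ids,
            "cross_accuracy": self.cross_accuracy,
            "passing_parameters": self.passing_parameters,
            "mean_rrmse_by_set": {k: float(np.mean(v)) for k, v in by_set.items()},
        }


def _parameter_values(meta_frame: pd.DataFrame, rel: AbundanceTable, parameter: str) -> np.ndarray:
    if parameter == "observed_asvs":
        sub = rel.data.loc[meta_frame["sample_id"]]
        return np.array([observed_asvs(r) for r in sub.to_numpy()], dtype=float)
    return meta_frame[parameter].to_numpy(dtype=float)


def run_two_step_workflow(
    abundance: AbundanceTable,
    metadata: SampleMetadata,
    config: WorkflowConfig | None = None,
) -> WorkflowResult:
    """Run selection (step 1) and prediction (step 2) for both A/B orientations."""
    cfg = config or WorkflowConfig()
    rel = to_relative(abundance) if abundance.mode == "counts" else abundance
    meta = assign_interval_and_label(metadata).frame
    labeled = meta[meta["hrt_label"].notna()]
    reactors = sorted(meta["reactor"].unique())
    if len(reactors) != 2:
        raise ValueError(f"expected two reactors, got {reactors}")

    def features_of(frame: pd.DataFrame) -> pd.DataFrame:
        return rel.data.loc[frame["sample_id"]].astype(float)

    # ---- step 1: HRT bioindicators per reactor -----------------------------
    hrt_sets: dict[str, sel.BioindicatorSet] = {}
    cross_accuracy: dict[str, float] = {}
    oob_errors: dict[str, float] = {}
    models = {}
    for train in reactors:
        test = [r for r in reactors if r != train][0]
        tr = labeled[labeled["reactor"] == train]
        te = labeled[labeled["reactor"] == test]
        spec = sel.RFClassifierSpec(cfg.n_trees, cfg.m_try_classifier, cfg.seed)
        model, oob, _ = sel.train_hrt_classifier(features_of(tr), tr["hrt_label"], spec)
        models[train] = model
        oob_errors[train] = oob
        cross_accuracy[f"{train}->{test}"] = sel.heldout_accuracy(
            model, features_of(te), te["hrt_label"]
        )
        trace = sel.recursive_gini_elimination(features_of(tr), tr["hrt_label"], spec)
        hrt_sets[train] = sel.select_bioindicators(
            trace, cfg.threshold_share, cfg.top_k, train_reactor=train
        )
    shared = sel.shared_set(hrt_sets[reactors[0]], hrt_sets[reactors[1]])

    # ---- step 2: gates, non-HRT sets, time-independent set ------------------
    reg_spec = pred.RFRegressorSpec(
        n_trees=cfg.n_trees_regression or cfg.n_trees, seed=cfg.seed
    )
    gate_rows = []
    nonhrt_sets: dict[tuple[str, str], sel.BioindicatorSet] = {}
    passing: list[str] = []
    frames = {r: labeled[labeled["reactor"] == r] for r in reactors}

    for parameter in cfg.parameters:
        if parameter != "observed_asvs" and parameter not in meta.columns:
            continue
        # gate a: the HRT bioindicators (shared set) must explain >80% OOB
        # variance on both training reactors
        expl_hrt = {}
        ok = True
        for train in reactors:
            X = features_of(frames[train])[shared.asv_ids]
            y = _parameter_values(frames[train], rel, parameter)
            if np.var(y) == 0 or len(shared) == 0:
                ok = False
                expl_hrt[train] = float("-inf")
                continue
            model = pred._fit_regressor(X.to_numpy(), y, reg_spec)
            expl_hrt[train] = pred.oob_explained_variance(model, y)
            ok = ok and expl_hrt[train] > cfg.variance_gate
        expl_non = {r: float("nan") for r in reactors}
        if ok:
            # gate b: non-HRT bioindicators, selected over all ASVs, must pass too
            for train in reactors:
                y = _parameter_values(frames[train], rel, parameter)
                nh = pred.select_nonhrt_bioindicators(
                    features_of(frames[train]), y, reg_spec, k=cfg.top_k,
                    parameter=parameter, train_reactor=train,
                )
                nonhrt_sets[(parameter, train)] = nh
                model = pred._fit_regressor(
                    features_of(frames[train])[nh.asv_ids].to_numpy(), y, reg_spec
                )
                expl_non[train] = pred.oob_explained_variance(model, y)
                ok = ok and expl_non[train] > cfg.variance_gate
        if ok:
            passing.append(parameter)
        gate_rows.append({
            "parameter": parameter,
            **{f"expl_hrt_{r}": expl_hrt.get(r) for r in reactors},
            **{f"expl_nonhrt_{r}": expl_non.get(r) for r in reactors},
            "passes": ok,
        })
    gate_table = pd.DataFrame(gate_rows)

    # the time-independent set is per target parameter: HRT bioindicators
    # absent from that parameter's non-HRT sets (both reactors)
    eval_params = [p for p in passing if p in cfg.eval_parameters] or []
    ti_per_param: dict[str, sel.BioindicatorSet] = {}
    for parameter in passing:
        sets = [nonhrt_sets[(parameter, r)] for r in reactors if (parameter, r) in nonhrt_sets]
        ti_per_param[parameter] = pred.time_independent_set(shared, sets)
    if eval_params:
        consensus = set(ti_per_param[eval_params[0]].asv_ids)
        for parameter in eval_params[1:]:
            consensus &= set(ti_per_param[parameter].asv_ids)
        ti_set = sel.BioindicatorSet(
            asv_ids=[a for a in shared.asv_ids if a in consensus],
            train_reactor=shared.train_reactor,
            target="HRT-irrespective-of-time",
            importances={a: shared.importances.get(a, 0.0) for a in consensus},
        )
    else:
        ti_set = sel.BioindicatorSet([], shared.train_reactor, "HRT-irrespective-of-time")

    # ---- evaluation: replicate RRMSE + full-set prediction reports ----------
    result = WorkflowResult(
        hrt_sets=hrt_sets, shared=shared, cross_accuracy=cross_accuracy,
        oob_errors=oob_errors, nonhrt_sets=nonhrt_sets, gate_table=gate_table,
        passing_parameters=passing, time_independent_per_parameter=ti_per_param,
        time_independent=ti_set,
    )
    all_frames = {r: meta[meta["reactor"] == r] for r in reactors}
    for parameter in eval_params:
        for train in reactors:
            test = [r for r in reactors if r != train][0]
            y_tr = _parameter_values(frames[train], rel, parameter)
            y_te = _parameter_values(frames[test], rel, parameter)
            X_tr, X_te = features_of(frames[train]), features_of(frames[test])
            # full-set report (labeled intervals), using the shared set
            result.prediction_reports.append(pred.rf_regress(
                X_tr[shared.asv_ids], y_tr,
                X_te[shared.asv_ids], y_te,
                reg_spec, parameter=parameter,
                train_reactor=train, test_reactor=test,
            ))
            # the HRT replicate evaluation subsamples the shared set (the
            # "HRT bioindicators" proper); non-HRT uses the per-reactor set
            for set_obj, sub in (
                (shared, cfg.subsample_hrt),
                (nonhrt_sets.get((parameter, train)), cfg.subsample_nonhrt),
            ):
                if set_obj is None:
                    continue
                sub = min(sub, len(set_obj))
                result.replicate_reports.append(pred.replicate_rrmse(
                    X_tr[set_obj.asv_ids], y_tr, X_te[set_obj.asv_ids], y_te,
                    set_obj, reg_spec, n_replicates=cfg.n_replicates,
                    subsample_size=sub, parameter=parameter,
                ))
            # all-phase control with the HRT set
            y_tr_all = _parameter_values(all_frames[train], rel, parameter)
            y_te_all = _parameter_values(all_frames[test], rel, parameter)
            result.prediction_reports.append(pred.rf_regress(
                features_of(all_frames[train])[shared.asv_ids], y_tr_all,
                features_of(all_frames[test])[shared.asv_ids], y_te_all,
                reg_spec, parameter=f"{parameter} (all phases)",
                train_reactor=train, test_reactor=test,
            ))
    return result
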