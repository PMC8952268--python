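"""Pipeline orchestration: YAML config, validation, manifest, full run.

A :class:`PipelineConfig` either points at input tables (abundance, metadata,
optional taxonomy) or embeds a :class:`~bioind.simulate.SimulationConfig`;
exactly one of the two must be active.  :func:`run` executes
simulate/load -> diversity -> two-step workflow -> co-occurrence network and
writes a deterministic directory layout with a manifest recording the seed
and a SHA-256 hash of every artifact.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import network as net
from .diversity import bray_curtis, nmds, observed_asvs, permanova, shannon
from .simulate import SimulationConfig, simulate_experiment, write_fixture
from .tables import (
    AbundanceTable,
    SampleMetadata,
    TaxonomyTable,
    assign_interval_and_label,
    rarefy,
    read_abundance_table,
    read_metadata,
    read_taxonomy_table,
    to_relative,
)
from .workflow import WorkflowConfig, run_two_step_workflow

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "bioind_out"
    abundance_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    simulation: SimulationConfig | None = None
    workflow: WorkflowConfig | None = None
    rarefaction_depth: int | None = None
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        has_paths = self.abundance_path is not None or self.metadata_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ValueError("exactly one of input paths or a simulation config must be set")
        if has_paths and (self.abundance_path is None or self.metadata_path is None):
            raise ValueError("both abundance_path and metadata_path are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        wf = raw.pop("workflow", None)
        cfg = cls(
            simulation=SimulationConfig(**sim) if sim is not None else None,
            workflow=WorkflowConfig(**wf) if wf is not None else None,
            **raw,
        )
        return cfg


def validate_inputs(
    abundance: AbundanceTable,
    metadata: SampleMetadata,
    taxonomy: TaxonomyTable | None = None,
) -> dict:
    """Cross-check ids across tables; summarize HRT class balance."""
    ab_ids = set(abundance.sample_ids)
    md_ids = set(metadata.sample_ids)
    if ab_ids != md_ids:
        only_ab = sorted(ab_ids - md_ids)[:5]
        only_md = sorted(md_ids - ab_ids)[:5]
        raise ValueError(
            f"sample id mismatch: only in abundance {only_ab}, only in metadata {only_md}"
        )
    if taxonomy is not None:
        missing = taxonomy.covers(abundance)
        if missing:
            raise ValueError(f"taxonomy missing ASVs: {missing}")
    labeled = assign_interval_and_label(metadata).frame
    counts = labeled["hrt_label"].value_counts(dropna=True).to_dict()
    report = {
        "status": "OK",
        "n_samples": len(ab_ids),
        "n_asvs": len(abundance.asv_ids),
        "labeled_counts": {str(k): int(v) for k, v in counts.items()},
    }
    logger.info("validation OK: %s", report)
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(config.out_dir)
    tables_dir, reports_dir = out / "tables", out / "reports"
    tables_dir.mkdir(parents=True, exist_ok=True)
    reports_dir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        if config.simulation is not None:
            stage = "simulate"
            bundle = simulate_experiment(config.simulation)
            abundance, metadata, truth = bundle
            write_fixture(bundle, tables_dir)
            taxonomy = None
        else:
            abundance = read_abundance_table(config.abundance_path)
            metadata = read_metadata(config.metadata_path)
            taxonomy = (
                read_taxonomy_table(config.taxonomy_path)
                if config.taxonomy_path
                else None
            )
            truth = None

        stage = "validate"
        validation = validate_inputs(abundance, metadata, taxonomy)

        stage = "rarefy"
        counts = abundance
        if counts.mode == "counts":
            depth = config.rarefaction_depth or int(counts.values().sum(axis=1).min())
            counts = rarefy(counts, depth, seed=config.seed)
            metadata = SampleMetadata(
                metadata.frame[metadata.frame["sample_id"].isin(counts.sample_ids)]
                .reset_index(drop=True)
            )
        rel = to_relative(counts)

        stage = "diversity"
        rows = counts.values()
        alpha = pd.DataFrame({
            "sample_id": counts.sample_ids,
            "observed_asvs": [observed_asvs(r) for r in rows],
            "shannon": [shannon(r) for r in rows],
        })
        alpha.to_csv(tables_dir / "alpha_diversity.tsv", sep="\t", index=False)
        dm = bray_curtis(counts)
        dm.to_frame().to_csv(tables_dir / "bray_curtis.tsv", sep="\t")
        coords, stress = nmds(dm, seed=config.seed)
        coords.to_csv(tables_dir / "nmds.tsv", sep="\t")
        labeled = assign_interval_and_label(metadata).frame
        lab_mask = labeled["hrt_label"].notna()
        diversity_report = {"nmds_stress": stress}
        if lab_mask.sum() >= 4 and labeled.loc[lab_mask, "hrt_label"].nunique() == 2:
            ids = list(labeled.loc[lab_mask, "sample_id"])
            sub = dm.to_frame().loc[ids, ids]
            from .diversity import DistanceMatrix

            res = permanova(
                DistanceMatrix(ids, sub.to_numpy()),
                list(labeled.loc[lab_mask, "hrt_label"]),
                n_permutations=config.n_permutations,
                seed=config.seed,
                factor="hrt_label",
            )
            diversity_report["permanova"] = {
                "pseudo_F": res.pseudo_f, "p": res.p_value, "factor": res.factor,
            }

        stage = "workflow"
        wf_cfg = config.workflow or WorkflowConfig(seed=config.seed)
        result = run_two_step_workflow(counts, metadata, wf_cfg)
        summary = result.summary()
        if truth is not None:
            planted = set(truth.responder_asv_ids)
            summary["recovery"] = {
                "responders_in_shared": len(planted & set(result.shared.asv_ids)),
                "n_planted": len(planted),
                "time_independent_recovered": len(
                    set(truth.time_independent_ids) & set(result.time_independent.asv_ids)
                ),
                "n_time_independent_planted": len(truth.time_independent_ids),
            }
        result.gate_table.to_csv(tables_dir / "variance_gates.tsv", sep="\t", index=False)
        for name, s in result.hrt_sets.items():
            s.to_frame(taxonomy).to_csv(
                tables_dir / f"hrt_bioindicators_{name}.tsv", sep="\t", index=False
            )
        result.shared.to_frame(taxonomy).to_csv(
            tables_dir / "hrt_bioindicators_shared.tsv", sep="\t", index=False
        )

        stage = "network"
        abiotic_cols = [
            c for c in ("hrt", "conc_lactate", "conc_C4", "conc_C6", "conc_C8",
                        "prod_C4", "prod_C6", "prod_C8",
                        "yield_C4", "yield_C6", "yield_C8")
            if c in metadata.frame.columns
        ]
        abiotic = metadata.frame.set_index("sample_id")[abiotic_cols]
        network = net.cooccurrence_network(counts.data.astype(float), abiotic)
        net.export_gexf(network, tables_dir / "network.gexf")
        net.export_edge_list(network, tables_dir / "network_edges.tsv")

        report = {
            "seed": config.seed,
            "validation": validation,
            "diversity": diversity_report,
            "workflow": summary,
            "network": {
                "n_nodes": network.graph.number_of_nodes(),
                "n_edges": network.graph.number_of_edges(),
                "hubs": network.hubs(),
            },
        }
        (reports_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "artifacts": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
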