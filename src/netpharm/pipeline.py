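"""End-to-end orchestration: config validation, stage execution, run report.

The pipeline executes read -> common targets -> CT-OT build -> hub
extraction -> centralities -> median screen -> over-representation ->
disease-pathway mapping -> compound-target-pathway network -> docking
ratios, and emits a machine-readable report whose fields are pure
functions of (config, inputs) so identical runs produce identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set

from . import io as npio
from .downstream import (
    DEFAULT_RATIO_CUTOFFS,
    build_compound_key_target_network,
    build_ctp_network,
    docking_ratios,
)
from .enrichment import enrich, map_disease_pathways, top_pathways
from .network import build_ct_ot_network, common_targets, extract_hub_network
from .synthetic import SyntheticConfig, generate_dataset, write_dataset
from .topology import centralities, screen_key_targets

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "RunReport", "validate_config", "run_pipeline"]

DEFAULT_PARAMS = {
    "min_score": 0.4,
    "degree_fold": 2.0,
    "alpha": 0.05,
    "top_k": 15,
    "method": "ease",
    "adjust": "bh",
    "ratio_cutoffs": list(DEFAULT_RATIO_CUTOFFS),
}

INPUT_KEYS = ("compound_targets", "disease_targets", "ppi")
OPTIONAL_INPUT_KEYS = ("genesets", "disease_pathways", "docking")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    config_hash: str
    seed: Optional[int]
    params: Dict
    counts: Dict[str, int] = field(default_factory=dict)
    thresholds: Dict[str, float] = field(default_factory=dict)
    common_targets: List[str] = field(default_factory=list)
    key_targets: List[str] = field(default_factory=list)
    top_pathways: List[Dict] = field(default_factory=list)
    common_pathways: List[str] = field(default_factory=list)
    outputs: Dict[str, str] = field(default_factory=dict)
    warnings: Dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


def validate_config(config: Dict) -> List[str]:
    """Return a list of violations; an empty list means the config is ok."""
    violations: List[str] = []
    inputs = config.get("inputs")
    simulate = config.get("simulate")
    if inputs and simulate:
        violations.append("'inputs' and 'simulate' blocks are mutually exclusive")
    if not inputs and simulate is None:
        violations.append("config needs an 'inputs' or a 'simulate' block")
    if inputs:
        for key in INPUT_KEYS:
            path = inputs.get(key)
            if path is None:
                violations.append(f"inputs.{key} is required")
            elif not Path(path).exists():
                violations.append(f"inputs.{key}: file not found: {path}")
        for key in OPTIONAL_INPUT_KEYS:
            path = inputs.get(key)
            if path is not None and not Path(path).exists():
                violations.append(f"inputs.{key}: file not found: {path}")
    if simulate is not None:
        try:
            SyntheticConfig(**simulate)
        except (TypeError, ValueError) as exc:
            violations.append(f"simulate: {exc}")
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    if not 0.0 <= params["min_score"] <= 1.0:
        violations.append(f"params.min_score must be in [0, 1]: {params['min_score']}")
    if not 0.0 < params["alpha"] < 1.0:
        violations.append(f"params.alpha must be in (0, 1): {params['alpha']}")
    if int(params["top_k"]) < 1:
        violations.append(f"params.top_k must be >= 1: {params['top_k']}")
    if params["degree_fold"] <= 0:
        violations.append(f"params.degree_fold must be > 0: {params['degree_fold']}")
    if params["method"] not in {"ease", "hypergeometric"}:
        violations.append(f"params.method unknown: {params['method']}")
    if params["adjust"] not in {"bh", "none"}:
        violations.append(f"params.adjust unknown: {params['adjust']}")
    cutoffs = params["ratio_cutoffs"]
    if not (len(cutoffs) == 2 and 0 < cutoffs[0] < cutoffs[1]):
        violations.append(f"params.ratio_cutoffs must be 0 < weak < strong: {cutoffs}")
    return violations


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc

    return wrap


def run_pipeline(config: Dict, outdir) -> RunReport:
    """Execute every configured stage and write outputs under ``outdir``."""
    violations = validate_config(config)
    if violations:
        raise PipelineError("validate_config", ValueError("; ".join(violations)))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()

    seed = None
    inputs = config.get("inputs")
    if config.get("simulate") is not None:
        sim_config = SyntheticConfig(**config["simulate"])
        seed = sim_config.seed
        dataset = _stage("simulate")(generate_dataset, sim_config)
        fixture_paths = _stage("simulate")(
            write_dataset, dataset, outdir / "fixtures"
        )
        inputs = {k: fixture_paths[k] for k in (*INPUT_KEYS, *OPTIONAL_INPUT_KEYS)}

    report = RunReport(config_hash=config_hash, seed=seed, params=params)
    outputs: Dict[str, str] = {}

    def _register(name: str, path: Path) -> Path:
        outputs[name] = str(path.relative_to(outdir))
        return path

    # --- load inputs ------------------------------------------------------
    ct = _stage("read_compound_targets")(
        npio.read_compound_targets, inputs["compound_targets"]
    )
    dt = _stage("read_disease_targets")(
        npio.read_disease_targets, inputs["disease_targets"]
    )
    edges = _stage("read_ppi_edges")(
        npio.read_ppi_edges, inputs["ppi"], min_score=params["min_score"]
    )
    report.counts.update(
        n_compounds=len(ct.compounds()),
        n_compound_targets=len(ct.all_targets()),
        n_disease_targets=len(dt.genes),
        n_ppi_edges=len(edges),
    )

    # --- networks ---------------------------------------------------------
    common = _stage("common_targets")(common_targets, ct, dt)
    report.common_targets = sorted(common)
    report.counts["n_common_targets"] = len(common)

    ctot = _stage("build_ct_ot_network")(
        build_ct_ot_network, ct, dt, edges, min_score=params["min_score"]
    )
    report.counts.update(ctot_nodes=ctot.n_nodes(), ctot_edges=ctot.n_edges())
    npio.write_network(ctot, _register("ctot", outdir / "ctot.graphml"))

    hub = _stage("extract_hub_network")(extract_hub_network, ctot, common)
    report.counts.update(hub_nodes=hub.n_nodes(), hub_edges=hub.n_edges())
    npio.write_network(hub, _register("hub", outdir / "hub.graphml"))

    # --- topology screen --------------------------------------------------
    table = _stage("centralities")(centralities, hub)
    screening = _stage("screen_key_targets")(
        screen_key_targets, table, degree_fold=params["degree_fold"]
    )
    report.thresholds = {
        "degree": screening.degree_cutoff,
        "betweenness": screening.betweenness_cutoff,
        "closeness": screening.closeness_cutoff,
    }
    report.key_targets = sorted(screening.key_targets)
    report.counts["n_key_targets"] = len(screening.key_targets)
    table_out = table.copy()
    table_out["is_key"] = table_out.index.isin(screening.key_targets)
    table_out.to_csv(
        _register("key_targets", outdir / "key_targets.tsv"), sep="\t",
        float_format="%.10g",
    )

    key_net = _stage("compound_key_target_network")(
        build_compound_key_target_network, ct, screening.key_targets, hub
    ) if screening.key_targets else None
    if key_net is not None:
        npio.write_network(
            key_net, _register("compound_key_target", outdir / "compound_key_targets.graphml")
        )

    # --- enrichment -------------------------------------------------------
    selected_names: List[str] = []
    if inputs.get("genesets") and not screening.key_targets:
        logger.warning("no key targets survived the screen; enrichment skipped")
        report.warnings["no_key_targets"] = 1
    elif inputs.get("genesets"):
        collection = _stage("read_gmt")(npio.read_gmt, inputs["genesets"])
        results = _stage("enrich")(
            enrich,
            screening.key_targets,
            collection,
            method=params["method"],
            adjust=params["adjust"],
        )
        top = top_pathways(
            results,
            k=int(params["top_k"]),
            alpha=params["alpha"],
            use_adjusted=params["adjust"] == "bh",
        )
        report.top_pathways = [
            {"name": r.set_name, "k": r.k, "K": r.K, "p_raw": r.p_raw, "p_adj": r.p_adj}
            for r in top
        ]
        with _register("enrichment", outdir / "enrichment.tsv").open("w") as fh:
            fh.write("set_name\tk\tK\tn\tN\tp_raw\tp_adj\tfold_enrichment\n")
            for r in results:
                fh.write(
                    f"{r.set_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                    f"{r.p_raw:.10g}\t{r.p_adj:.10g}\t{r.fold_enrichment:.10g}\n"
                )
        if inputs.get("disease_pathways"):
            disease = npio.read_gene_list(inputs["disease_pathways"])
            mapped = map_disease_pathways(top, disease)
            report.common_pathways = [r.set_name for r in mapped]
            selected_names = [r.set_name for r in mapped]
        if selected_names and screening.key_targets:
            membership = {
                name: set(collection[name].members) for name in selected_names
            }
            ctp = _stage("build_ctp_network")(
                build_ctp_network, ct, screening.key_targets, membership,
                selected_names,
            )
            import networkx as nx

            nx.write_graphml(
                ctp.graph, _register("ctp", outdir / "ctp.graphml")
            )
        else:
            report.warnings["no_common_pathways"] = 1

    # --- docking ----------------------------------------------------------
    if inputs.get("docking"):
        dock = _stage("read_docking_table")(
            npio.read_docking_table, inputs["docking"]
        )
        matrix = _stage("docking_ratios")(
            docking_ratios, dock, cutoffs=tuple(params["ratio_cutoffs"])
        )
        matrix.ratios.to_csv(
            _register("docking_ratios", outdir / "docking_ratios.csv"),
            index_label="compound", float_format="%.10g",
        )
        matrix.categories.to_csv(
            _register("docking_categories", outdir / "docking_categories.csv"),
            index_label="compound",
        )
        report.warnings["missing_docking_cells"] = int(
            matrix.ratios.isna().to_numpy().sum()
        )

    report.outputs = outputs
    report_path = outdir / "report.json"
    report.outputs["report"] = report_path.name
    report_path.write_text(report.to_json())
    return report
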