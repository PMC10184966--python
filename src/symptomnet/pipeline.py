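"""End-to-end analysis pipeline and machine-readable report.

Stages: descriptives/prevalence -> EBIC-glasso network -> centrality ->
(optional) bootstrap + case-dropping stability -> (optional) covariate
adjustment -> (optional) permutation group comparisons.  All outputs are
plain TSV/JSON/GraphML; the report validates against the JSON schema shipped
as ``report_schema.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import scales
from .comparison import group_split, nct
from .errors import ValidationError
from .model import SymptomNetworkModel
from .scales import ALL_ITEMS, GAD_ITEMS, PSQI_ITEMS
from .simulate import GeneratorConfig, sample_ordinal

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline` (YAML/JSON loadable)."""

    input_path: str | None = None        # CSV/TSV of respondents; or simulate
    simulate_n: int | None = None        # generate data instead of reading
    out_dir: str = "symptomnet_out"
    seed: int = 0
    cor_method: str = "polychoric"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    bootstrap_B: int = 0                 # 0 disables
    cs_B: int = 0                        # 0 disables
    cs_grid: tuple = (0.10, 0.25, 0.50, 0.75)
    covariates: list = field(default_factory=list)
    nct_group_var: str | None = None
    nct_rule: dict | None = None
    nct_permutations: int = 1000

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.input_path is None and self.simulate_n is None:
            raise ValidationError("config needs input_path or simulate_n")
        if self.nct_group_var is not None and not self.nct_rule:
            raise ValidationError("NCT requested but nct_rule (category->arm map) missing")
        if self.nct_rule is not None and self.nct_group_var is None:
            raise ValidationError("nct_rule given without nct_group_var")


def _load_input(config: PipelineConfig) -> pd.DataFrame:
    if config.simulate_n is not None:
        return sample_ordinal(GeneratorConfig(n=config.simulate_n, seed=config.seed))
    path = Path(config.input_path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ALL_ITEMS if c not in df.columns]
    if missing:
        raise ValidationError(f"input lacks item columns: {missing}")
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the report dict and writes files."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    data = _load_input(config)
    logger.info("stage=load rows=%d wall=%.2fs", len(data), time.time() - t0)

    report: dict = {
        "meta": {
            "seed": int(config.seed),
            "n": int(len(data)),
            "items": list(ALL_ITEMS),
        }
    }

    # -- scales ------------------------------------------------------------
    t = time.time()
    desc = scales.describe_items(data)
    desc.to_csv(out / "descriptives.tsv", sep="\t")
    gad_total = data[GAD_ITEMS].sum(axis=1)
    psqi_total = data[PSQI_ITEMS].sum(axis=1)
    n = len(data)
    prev = {
        "anxiety": scales.prevalence_ci(int((gad_total >= 5).sum()), n),
        "poor_sleep": scales.prevalence_ci(int((psqi_total > 7).sum()), n),
        "clinical_sleep": scales.prevalence_ci(int((psqi_total >= 10).sum()), n),
    }
    report["descriptives"] = desc.reset_index().to_dict(orient="records")
    report["prevalence"] = {k: dataclasses.asdict(v) for k, v in prev.items()}
    (out / "prevalence.json").write_text(json.dumps(report["prevalence"], indent=2))
    logger.info("stage=scales wall=%.2fs", time.time() - t)

    # -- network -----------------------------------------------------------
    t = time.time()
    model = SymptomNetworkModel(
        data,
        cor_method=config.cor_method,
        gamma=config.gamma,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    res = model.fit()
    net = res.network
    net.write_edge_list(out / "network_edges.tsv")
    net.write_graphml(out / "network.graphml")
    res.ebic_trace.write_tsv(out / "ebic_trace.tsv")
    report["network"] = {
        "lambda": float(net.lambda_),
        "gamma": float(net.gamma),
        "ebic": float(net.ebic),
        "edge_count": int(net.edge_count),
        "edges": net.edge_frame().to_dict(orient="records"),
    }
    logger.info("stage=network edges=%d wall=%.2fs", net.edge_count, time.time() - t)

    # -- centrality --------------------------------------------------------
    t = time.time()
    tab = res.centrality()
    tab.to_csv(out / "centrality.tsv", sep="\t")
    report["centrality"] = tab.reset_index().to_dict(orient="records")
    report["top_symptoms"] = {
        "by_ei": res.rank(4, by="ei"),
        "by_bridge_ei": res.rank(4, by="bridge_ei") if "bridge_ei" in tab.columns else [],
    }
    logger.info("stage=centrality wall=%.2fs", time.time() - t)

    # -- stability ---------------------------------------------------------
    if config.bootstrap_B or config.cs_B:
        t = time.time()
        stab: dict = {}
        if config.bootstrap_B:
            boot = res.bootstrap(B=config.bootstrap_B, seed=config.seed)
            boot.edge_summary().to_csv(out / "bootstrap_edge_ci.tsv", sep="\t", index=False)
            np.savetxt(out / "edge_difference_matrix.tsv",
                       boot.edge_difference_test().astype(int), fmt="%d", delimiter="\t")
            stab["bootstrap_B"] = int(boot.B)
            stab["bootstrap_failures"] = int(boot.n_failed)
        if config.cs_B:
            cs = res.case_drop_stability(
                B=config.cs_B, seed=config.seed, drop_grid=tuple(config.cs_grid)
            )
            stab["cs_coefficient_ei"] = float(cs.cs_coefficient())
            stab["cs_summary"] = cs.summary().to_dict(orient="records")
            (out / "cs_summary.json").write_text(json.dumps(stab["cs_summary"], indent=2))
        report["stability"] = stab
        logger.info("stage=stability wall=%.2fs", time.time() - t)

    # -- covariate adjustment ---------------------------------------------
    if config.covariates:
        t = time.time()
        adj = res.adjusted_for(list(config.covariates))
        base = res
        if config.cor_method == "polychoric":
            # residuals are continuous, so compare same-method fits
            base = SymptomNetworkModel(
                data, cor_method="pearson", gamma=config.gamma,
                n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
            ).fit()
        cmp_ = base.compare_with(adj)
        report["adjusted_comparison"] = dataclasses.asdict(cmp_)
        adj.network.write_edge_list(out / "network_edges_adjusted.tsv")
        logger.info("stage=adjustment r=%.3f wall=%.2fs", cmp_.r_edges, time.time() - t)

    # -- NCT ---------------------------------------------------------------
    if config.nct_group_var:
        t = time.time()
        a, b = group_split(data, config.nct_group_var, config.nct_rule)
        r = nct(
            a, b, n_perm=config.nct_permutations, seed=config.seed,
            items=list(ALL_ITEMS),
            cor_method=config.cor_method, gamma=config.gamma,
            n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
        )
        report["nct"] = {
            "group_var": config.nct_group_var,
            "n_a": int(len(a)),
            "n_b": int(len(b)),
            "m": r.m_observed,
            "s": r.s_observed,
            "p_m": r.p_m,
            "p_s": r.p_s,
            "n_perm": r.n_perm,
        }
        r.edge_table.to_csv(out / "nct_edges.tsv", sep="\t", index=False)
        r.significant_edges().to_csv(out / "nct_significant_edges.tsv", sep="\t", index=False)
        logger.info("stage=nct p_m=%.4f wall=%.2fs", r.p_m, time.time() - t)

    validate_report(report)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    logger.info("pipeline done wall=%.2fs", time.time() - t0)
    return report


def load_report_schema() -> dict:
    with resources.files("symptomnet").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Check the report against the shipped schema.

    A minimal structural validator (required keys and JSON types, one level
    of ``$ref`` into ``$defs``); raises :class:`ValidationError` on mismatch.
    """
    schema = schema or load_report_schema()
    defs = schema.get("$defs", {})

    def resolve(node):
        if "$ref" in node:
            return defs[node["$ref"].rsplit("/", 1)[-1]]
        return node

    def check(node, value, path):
        node = resolve(node)
        typ = node.get("type")
        jstype = {
            "object": dict, "array": list, "string": str,
            "integer": int, "number": (int, float), "boolean": bool,
        }.get(typ)
        if jstype is not None and not isinstance(value, jstype):
            raise ValidationError(f"report{path}: expected {typ}, got {type(value).__name__}")
        if typ == "object":
            for req in node.get("required", []):
                if req not in value:
                    raise ValidationError(f"report{path}: missing required key {req!r}")
            for key, sub in node.get("properties", {}).items():
                if key in value:
                    check(sub, value[key], f"{path}.{key}")
        elif typ == "array" and "items" in node:
            for i, item in enumerate(value):
                check(node["items"], item, f"{path}[{i}]")

    check(schema, report, "")
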