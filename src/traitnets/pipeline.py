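"""End-to-end workflows: build, compare, null-test.

These functions are thin orchestration over the library modules; the CLI
calls them and they are equally usable from Python. Every run writes a
machine-readable ``provenance.json`` (config echo plus a step-by-step
description) sufficient to rerun the exact analysis, and a human log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .construction import (
    build_trait_network,
    write_edge_list,
    write_graphml,
    write_node_table,
)
from .inference import (
    BootstrapEnsemble,
    bootstrap_ensemble,
    compare_groups,
    er_null_ensemble,
    permutation_pvalue,
)
from .matrices import (
    CWMMatrix,
    compute_cwm,
    direct_trait_matrix,
    expand_traits,
    read_site_species_csv,
    read_trait_table_csv,
    write_cwm_csv,
)
from .metrics import METRIC_NAMES, compute_metrics

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_build", "run_compare", "run_null_test"]

# settings that must match between two runs for a comparison to be fair
_PIPELINE_KEYS = (
    "mode", "community_mode", "r_star", "alpha", "rule", "signed",
    "within_trait", "p_adjust", "module_algorithm", "B_boot",
)


class RunConfig(BaseModel):
    """Configuration of one pipeline run.

    Unknown keys are rejected outright (a typo must not silently fall
    back to a default threshold). ``seed`` is mandatory whenever a
    stochastic step (bootstrap, null model, Louvain) is enabled.
    """

    model_config = ConfigDict(extra="forbid")

    trait_csv: str
    community_csv: Optional[str] = None
    mode: Literal["cwm", "direct"] = "cwm"
    community_mode: Literal["abundance", "presence"] = "abundance"
    delimiter: str = ","
    r_star: float = Field(default=0.2, ge=0.0, le=1.0)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    rule: Literal["p_and_r", "p_only", "r_only"] = "p_and_r"
    signed: Literal["abs", "positive_only"] = "abs"
    within_trait: bool = True
    p_adjust: Optional[Literal["bh"]] = None
    module_algorithm: Literal["greedy", "fastgreedy", "louvain"] = "greedy"
    B_null: int = Field(default=1000, ge=1)
    B_boot: int = Field(default=1000, ge=1)
    seed: Optional[int] = None
    out_dir: str = "traitnet_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def require_seed(self, step: str) -> int:
        if self.seed is None:
            raise ValueError(f"{step} is stochastic: config must set a seed")
        return self.seed


def _setup_outputs(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="a", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("traitnets")
    root.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler)
               and getattr(h, "baseFilename", None) == str((out / "run.log").resolve())
               for h in root.handlers):
        root.addHandler(handler)
    return out


def _observations(config: RunConfig, out: Path | None = None, steps: list | None = None
                  ) -> CWMMatrix:
    """Read inputs and produce the observation x trait-value matrix."""
    table = read_trait_table_csv(config.trait_csv, delimiter=config.delimiter)
    tvm = expand_traits(table)
    if steps is not None:
        steps.append(
            f"expanded {len(table.traits)} categorical traits of "
            f"{len(table.species)} species into {tvm.values.shape[1]} binary trait values"
        )
    if config.mode == "cwm":
        if config.community_csv is None:
            raise ValueError("mode 'cwm' requires community_csv")
        community = read_site_species_csv(
            config.community_csv, mode=config.community_mode, delimiter=config.delimiter
        )
        obs = compute_cwm(community, tvm)
        if steps is not None:
            steps.append(
                f"computed community-weighted means over {len(community.sites)} sites "
                f"({config.community_mode} weights)"
            )
        if out is not None:
            write_cwm_csv(obs, out / "cwm.csv")
    else:
        obs = direct_trait_matrix(tvm)
        if steps is not None:
            steps.append(
                "used the species x trait-value matrix directly "
                f"({len(tvm.species)} species as observations; no site structure)"
            )
    return obs


def _network_kwargs(config: RunConfig) -> dict:
    return dict(
        r_star=config.r_star, alpha=config.alpha, rule=config.rule,
        signed=config.signed, within_trait=config.within_trait,
        p_adjust=config.p_adjust,
    )


def _write_provenance(out: Path, config: RunConfig, steps: list, extra: dict | None = None) -> None:
    payload = {
        "traitnets_version": __version__,
        "config": config.model_dump(),
        "steps": steps,
    }
    payload.update(extra or {})
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")


def run_build(config: RunConfig) -> dict:
    """trait table (+ community) -> network -> metrics, with all exports."""
    out = _setup_outputs(config)
    steps: list[str] = []
    obs = _observations(config, out, steps)
    G = build_trait_network(obs, **_network_kwargs(config))
    steps.append(
        f"Pearson-correlated trait values over {obs.values.shape[0]} observations; "
        f"kept pairs passing rule={config.rule} (r*={config.r_star}, alpha={config.alpha}, "
        f"{config.signed}); network has {G.number_of_nodes()} nodes, {G.number_of_edges()} edges"
    )
    seed = (config.require_seed("louvain module detection")
            if config.module_algorithm == "louvain" else None)
    report = compute_metrics(G, algorithm=config.module_algorithm, seed=seed)
    steps.append(
        f"metrics: edge_density={report.edge_density:.4f}, Q={report.modularity_Q:.4f} "
        f"({report.n_modules} modules), centralization={report.degree_centralization:.4f}"
    )
    write_graphml(G, out / "network.graphml")
    write_edge_list(G, out / "edges.tsv")
    write_node_table(G, out / "nodes.csv")
    report.to_json(out / "metrics.json")
    report.to_csv(out / "metrics.csv")
    report.modules_to_csv(out / "modules.csv")
    _write_provenance(out, config, steps)
    logger.info("build complete: %s", out)
    return {"network": G, "metrics": report, "out_dir": out, "observations": obs}


def run_compare(config_a: RunConfig, config_b: RunConfig,
                metrics: tuple[str, ...] = METRIC_NAMES) -> dict:
    """Bootstrap both groups and compare every metric.

    Refuses to run if the two configs differ in any pipeline setting
    (threshold, rule, mode, B_boot, ...): comparing networks built under
    different rules would confound the group difference with the
    methodological one.
    """
    mismatched = [k for k in _PIPELINE_KEYS
                  if getattr(config_a, k) != getattr(config_b, k)]
    if mismatched:
        raise ValueError(
            "configs differ in pipeline settings, comparison would be "
            f"confounded: {mismatched}"
        )
    if config_a.B_boot < 2:
        raise ValueError("B_boot must be >= 2 for a comparison (tests undefined at B=1)")
    out = _setup_outputs(config_a)
    steps: list[str] = []
    obs_a = _observations(config_a, None, steps)
    obs_b = _observations(config_b, None, steps)
    seed_a = config_a.require_seed("bootstrap")
    seed_b = config_b.require_seed("bootstrap")
    if (config_a.trait_csv == config_b.trait_csv
            and config_a.community_csv == config_b.community_csv):
        # self-comparison sanity mode: identical seeds give identical ensembles
        pass
    kw = _network_kwargs(config_a)
    kw.pop("p_adjust", None)
    ens_a = bootstrap_ensemble(obs_a, B=config_a.B_boot, seed=seed_a,
                               metrics=metrics, algorithm=config_a.module_algorithm, **kw)
    ens_b = bootstrap_ensemble(obs_b, B=config_b.B_boot, seed=seed_b,
                               metrics=metrics, algorithm=config_b.module_algorithm, **kw)
    steps.append(f"bootstrapped both groups {config_a.B_boot} times "
                 f"({config_a.B_boot * 2} networks total)")
    results = {m: compare_groups(ens_a, ens_b, m) for m in metrics}

    ens_a.metrics.to_csv(out / "bootstrap_a.csv", index_label="replicate")
    ens_b.metrics.to_csv(out / "bootstrap_b.csv", index_label="replicate")
    with open(out / "comparison.json", "w", encoding="utf-8") as fh:
        json.dump({m: r.to_dict() for m, r in results.items()}, fh, indent=2)
        fh.write("\n")
    with open(out / "comparison.txt", "w", encoding="utf-8") as fh:
        for r in results.values():
            fh.write(r.summary() + "\n")
    _write_provenance(out, config_a, steps,
                      extra={"config_b": config_b.model_dump()})
    logger.info("comparison complete: %s", out)
    return {"ensemble_a": ens_a, "ensemble_b": ens_b, "results": results, "out_dir": out}


def run_null_test(config: RunConfig, metrics: tuple[str, ...] = METRIC_NAMES) -> dict:
    """Observed network vs Erdős–Rényi G(n, m) nulls, per metric."""
    out = _setup_outputs(config)
    steps: list[str] = []
    obs = _observations(config, None, steps)
    G = build_trait_network(obs, **_network_kwargs(config))
    mseed = config.seed if config.module_algorithm == "louvain" else None
    observed = compute_metrics(G, algorithm=config.module_algorithm, seed=mseed)
    seed = config.require_seed("Erdős–Rényi null ensemble")
    null = er_null_ensemble(G, B=config.B_null, seed=seed,
                            metrics=metrics, algorithm=config.module_algorithm)
    steps.append(f"generated {config.B_null} G(n={null.n_nodes}, m={null.n_edges}) "
                 "null networks")

    rows = {}
    degenerate = G.number_of_edges() == 0
    for name in metrics:
        obs_val = getattr(observed, name) if name != "n_modules" else observed.n_modules
        nulls = null.metrics[name]
        if np.isnan(obs_val) or nulls.isna().all():
            rows[name] = {"observed": float(obs_val), "p_greater": None,
                          "p_less": None, "significant": None}
            continue
        pg = permutation_pvalue(obs_val, nulls, side="greater")
        pl = permutation_pvalue(obs_val, nulls, side="less")
        rows[name] = {
            "observed": float(obs_val),
            "null_mean": float(nulls.mean()),
            "p_greater": pg,
            "p_less": pl,
            "significant_greater": pg < config.alpha,
            "significant_less": pl < config.alpha,
        }
    payload = {
        "n_nodes": null.n_nodes, "n_edges": null.n_edges, "B": null.B,
        "degenerate_null": degenerate, "metrics": rows,
    }
    if degenerate:
        payload["note"] = ("observed network has no edges: every null replicate is "
                          "the empty graph; all p-values are 1")
    null.metrics.to_csv(out / "null_metrics.csv", index_label="replicate")
    with open(out / "null_test.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    _write_provenance(out, config, steps, extra={"null_test": rows})
    logger.info("null test complete: %s", out)
    return {"network": G, "observed": observed, "null": null,
            "report": payload, "out_dir": out}
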