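"""End-to-end runs: config, stage orchestration, machine-readable summary.

A run executes the selected stages in dependency order (screen -> graph ->
enrichment; assay, colocalization and qPCR are independent), writes each
stage's outputs into the run directory and finishes with ``summary.json``
holding the headline numbers, the seed and a hash of the resolved config.
Stage failure aborts the run naming the stage; outputs of completed stages
are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import (colocalization, expression_qpcr, interactome_graph,
               silac_screen, synthetic_data, term_enrichment,
               trafficking_assay)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("epitrack")

_DEFAULTS: dict = {
    "stages": ["screen", "graph", "enrich", "assay", "qpcr"],
    "seed": 0,
    "out_dir": "epitrack_run",
    "screen": {"input": None, "min_fold": 3.0, "max_p": 0.05,
               "min_peptides": 2, "test": "two_sided_unpaired_intensity",
               "fdr": "none"},
    "graph": {"edges": None, "min_score": None},
    "enrich": {"gmt": None, "background": None, "fdr": 0.05, "top_terms": 15},
    "coloc": {"a": None, "b": None, "ta": 0.0, "tb": 0.0, "mask": None},
    "assay": {"events": None, "sign": "positive_recycling",
              "epsilon": 0.1},
    "qpcr": {"ct": None, "housekeeping": "GUSB", "reference": "D0"},
}


class RunConfig(dict):
    """Flat per-stage key-value configuration with defaults filled in."""

    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "RunConfig":
        cfg = cls()
        for key, value in _DEFAULTS.items():
            if isinstance(value, dict):
                cfg[key] = {**value, **(mapping or {}).get(key, {})}
            else:
                cfg[key] = (mapping or {}).get(key, value)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    cfg = RunConfig.from_mapping(yaml.safe_load(Path(path).read_text()) or {})
    for stage in cfg["stages"]:
        section = cfg.get(stage, {})
        for key in ("input", "edges", "gmt", "events", "ct"):
            p = section.get(key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"stage {stage!r}: path {p} not found")
    return cfg


def _stage_screen(cfg: RunConfig, out: Path, summary: dict) -> pd.DataFrame:
    section = cfg["screen"]
    table = (silac_screen.load_silac_table(section["input"])
             if section["input"] else silac_screen.load_table1_fixture())
    criteria = silac_screen.SelectionCriteria(
        min_fold=section["min_fold"], max_p=section["max_p"],
        min_unique_peptides=section["min_peptides"], test=section["test"],
        fdr=section["fdr"])
    result = silac_screen.select_interactors(table, criteria, seed=cfg["seed"])
    silac_screen.export_interactors(result, out / "interactors.tsv",
                                    selected_only=False)
    selected = result[result["selected"]]
    summary["screen"] = {
        "n_selected": int(result["selected"].sum()),
        "max_mean_ratio": float(selected["mean_ratio"].max()),
        "max_ratio_p": float(
            selected.loc[selected["mean_ratio"].idxmax(), "p_value"]),
    }
    return result


def _stage_graph(cfg: RunConfig, out: Path, summary: dict,
                 interactors: pd.DataFrame) -> None:
    section = cfg["graph"]
    if section["edges"] is None:
        log.warning("graph stage: no edge list supplied, skipping")
        return
    edges = interactome_graph.load_edge_list(section["edges"])
    g = interactome_graph.build_graph(interactors, edges,
                                      min_score=section["min_score"])
    partition, removals = interactome_graph.cluster_edge_betweenness(g)
    interactome_graph.partition_table(g, partition).to_csv(
        out / "communities.tsv", sep="\t", index=False)
    summary["graph"] = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_communities": len(set(partition.communities.values())),
        "modularity": partition.modularity,
    }


def _stage_enrich(cfg: RunConfig, out: Path, summary: dict,
                  interactors: pd.DataFrame) -> None:
    section = cfg["enrich"]
    if section["gmt"] is None:
        log.warning("enrich stage: no GMT supplied, skipping")
        return
    annotations = term_enrichment.read_gmt(section["gmt"])
    background = (Path(section["background"]).read_text().split()
                  if section["background"] else list(interactors.index))
    results = term_enrichment.enrich_terms(interactors, annotations,
                                           background, alpha=section["fdr"])
    results.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    chord = term_enrichment.chord_data(results, interactors, annotations,
                                       top_n=section["top_terms"])
    chord.to_csv(out / "chord_data.tsv", sep="\t", index=False)
    summary["enrich"] = {
        "n_terms_tested": len(results),
        "n_pass_fdr": int(results["pass_fdr"].sum()) if len(results) else 0,
        "chord_proteins": int(chord.attrs["n_included"]),
    }


def _stage_assay(cfg: RunConfig, out: Path, summary: dict) -> None:
    section = cfg["assay"]
    if section["events"] is None:
        params = synthetic_data.TraffickingParams(seed=cfg["seed"])
        events = synthetic_data.simulate_flow_panel(params)
    else:
        events = pd.read_csv(section["events"])
    report = trafficking_assay.analyze_panel(
        events, sign_convention=section["sign"])
    (out / "assay_report.json").write_text(json.dumps(report, indent=2))
    summary["assay"] = {
        "endocytosis_rate_pct": 100.0 * report["endocytosis_rate"],
        "recycling_rate_pct": 100.0 * report["recycling_rate"],
    }


def _stage_qpcr(cfg: RunConfig, out: Path, summary: dict) -> None:
    section = cfg["qpcr"]
    if section["ct"] is None:
        params = synthetic_data.QpcrSimParams(seed=cfg["seed"])
        ct = synthetic_data.simulate_qpcr(params)
    else:
        ct = expression_qpcr.load_ct_table(section["ct"])
    rq = expression_qpcr.delta_delta_ct(ct, section["housekeeping"],
                                        section["reference"])
    rq.to_csv(out / "relative_expression.tsv", sep="\t", index=False)
    grp = rq.drop_duplicates(["group", "gene"])
    summary["qpcr"] = {
        f"{g}/{gene}": float(v) for g, gene, v in
        zip(grp["group"], grp["gene"], grp["group_rq"])
    }


def _stage_coloc(cfg: RunConfig, out: Path, summary: dict) -> None:
    section = cfg["coloc"]
    if section["a"] is None or section["b"] is None:
        log.warning("coloc stage: no image pair supplied, skipping")
        return
    pair = colocalization.read_image_pair(section["a"], section["b"],
                                          section["ta"], section["tb"],
                                          section["mask"])
    res = colocalization.manders_coefficients(pair)
    summary["coloc"] = {"M1": res.M1, "M2": res.M2}


def run_pipeline(config: RunConfig | dict, out_dir: str | Path | None = None
                 ) -> dict:
    """Execute the configured stages and write ``summary.json``."""
    cfg = (config if isinstance(config, RunConfig)
           else RunConfig.from_mapping(config))
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    log.addHandler(handler)
    summary: dict = {"seed": cfg["seed"], "config_hash": cfg.config_hash()}
    interactors: pd.DataFrame | None = None
    try:
        for stage in cfg["stages"]:
            log.info("running stage %s", stage)
            try:
                if stage == "screen":
                    interactors = _stage_screen(cfg, out, summary)
                elif stage == "graph":
                    if interactors is None:
                        raise RuntimeError("graph stage needs screen output")
                    _stage_graph(cfg, out, summary, interactors)
                elif stage == "enrich":
                    if interactors is None:
                        raise RuntimeError("enrich stage needs screen output")
                    _stage_enrich(cfg, out, summary, interactors)
                elif stage == "assay":
                    _stage_assay(cfg, out, summary)
                elif stage == "qpcr":
                    _stage_qpcr(cfg, out, summary)
                elif stage == "coloc":
                    _stage_coloc(cfg, out, summary)
                else:
                    raise ValueError(f"unknown stage {stage!r}")
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float))
        log.removeHandler(handler)
        handler.close()
    return summary
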