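"""End-to-end pipeline: network build -> disease ranking -> drug scoring
-> evaluation -> class enrichment, with a provenance manifest.

The run configuration is one hierarchical mapping (typically loaded from
YAML); every stage writes its artifact into the output directory and the
manifest records parameters, input checksums, iteration counts and the
package version, so a rerun with identical config and inputs is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Sequence

from . import __version__
from .enrich import DECILE_CUTOFFS, class_distribution, top_class_enrichment
from .evaluate import DEFAULT_CUTOFFS, retrospective_eval
from .gdn import SIMILARITY_METHODS, build_gdn, column_normalize
from .kb_io import (
    read_associations,
    read_class_map,
    read_gold,
    read_treatment_kb,
)
from .reposition import de_novo_mask, remove_drugs, score_drugs
from .rwr import RWRParams, rank_from_matrix

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("gdnrepo")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    associations: str
    target: str
    treatment_kbs: Sequence[tuple[str, str]]  # (path, source tag)
    outdir: str
    dialect: str = "simple"
    similarity: str = "cosine"
    min_weight: float = 0.0
    gamma: float = 0.1
    tol: float = 1e-6
    max_iter: int = 10_000
    norm: str = "l1"
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS
    gold: Sequence[tuple[str, str]] = ()  # (path, label)
    exclude_drugs: str | None = None  # gold list removed before ranking (novel mode)
    disease_classes: str | None = None
    drug_classes: str | None = None
    top_fraction: float = 0.10
    min_fold: float = 2.0
    rwr_params: RWRParams = dc_field(init=False)

    def __post_init__(self) -> None:
        # RWRParams validates gamma/tol/max_iter/norm before any computation
        self.rwr_params = RWRParams(
            gamma=self.gamma, tol=self.tol, max_iter=self.max_iter, norm=self.norm
        )
        if self.similarity not in SIMILARITY_METHODS:
            raise ValueError(f"unknown similarity method {self.similarity!r}")
        if not (0 < self.top_fraction <= 1):
            raise ValueError(f"top_fraction {self.top_fraction} outside (0, 1]")
        for c in self.cutoffs:
            if not (0 < c <= 1):
                raise ValueError(f"cutoff fraction {c} outside (0, 1]")
        for p in self._input_paths():
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def _input_paths(self) -> list[str]:
        paths = [self.associations] + [p for p, _ in self.treatment_kbs]
        paths += [p for p, _ in self.gold]
        for p in (self.exclude_drugs, self.disease_classes, self.drug_classes):
            if p:
                paths.append(p)
        return paths

    @classmethod
    def from_mapping(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        if "treatment_kbs" in data:
            data["treatment_kbs"] = [tuple(x) for x in data["treatment_kbs"]]
        if "gold" in data:
            data["gold"] = [tuple(x) for x in data["gold"]]
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and return the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "parameters": {
            "target": config.target,
            "similarity": config.similarity,
            "min_weight": config.min_weight,
            "gamma": config.gamma,
            "tol": config.tol,
            "max_iter": config.max_iter,
            "norm": config.norm,
            "cutoffs": list(config.cutoffs),
            "top_fraction": config.top_fraction,
            "min_fold": config.min_fold,
        },
        "inputs": {p: _sha256(p) for p in config._input_paths()},
        "stages": [],
        "outputs": {},
    }

    current_stage = ""

    def _stage(name: str):
        nonlocal current_stage
        current_stage = name
        t0 = time.perf_counter()

        def done(**info: Any) -> None:
            dt = time.perf_counter() - t0
            log.info("stage %s finished in %.2fs", name, dt)
            manifest["stages"].append({"name": name, "seconds": round(dt, 3), **info})

        return done

    try:
        done = _stage("build-network")
        assoc = read_associations(config.associations, dialect=config.dialect)
        net = build_gdn(assoc, method=config.similarity, min_weight=config.min_weight)
        net.write_edgelist(outdir / "network_edges.tsv")
        manifest["outputs"]["network_edges"] = "network_edges.tsv"
        done(n_nodes=net.n_nodes, n_edges=net.n_edges, n_isolated=len(net.isolated_nodes))

        done = _stage("rank-diseases")
        M = column_normalize(net)
        ranking = rank_from_matrix(M, config.target, config.rwr_params)
        ranking.to_frame().to_csv(outdir / "disease_ranking.tsv", sep="\t", index=False)
        manifest["outputs"]["disease_ranking"] = "disease_ranking.tsv"
        done(n_ranked=len(ranking), iterations=ranking.iterations_used)

        done = _stage("reposition")
        kb = read_treatment_kb(config.treatment_kbs)
        masked = de_novo_mask(kb, config.target)
        drugs = score_drugs(ranking, masked)
        if config.exclude_drugs:
            excluded = read_gold(config.exclude_drugs, label="excluded")
            drugs = remove_drugs(drugs, excluded.drugs)
        drugs.write_tsv(outdir / "drug_ranking.tsv")
        manifest["outputs"]["drug_ranking"] = "drug_ranking.tsv"
        done(n_scored=len(drugs), universe=drugs.universe_size)

        done = _stage("evaluate")
        eval_info = {}
        for path, label in config.gold:
            gold = read_gold(path, label=label)
            report = retrospective_eval(drugs, gold, config.cutoffs)
            name = f"evaluation_{label or 'gold'}.json"
            report.write_json(outdir / name)
            manifest["outputs"][f"evaluation_{label or 'gold'}"] = name
            eval_info[label or "gold"] = {
                "recall": report.recall_overall,
                "median_percentile": report.median_percentile,
            }
        done(**eval_info)

        done = _stage("enrich")
        info = {}
        if config.disease_classes:
            cmap = read_class_map(config.disease_classes)
            dist = class_distribution(list(ranking.diseases), cmap, DECILE_CUTOFFS)
            dist.to_csv(outdir / "disease_class_distribution.tsv", sep="\t", index=False)
            manifest["outputs"]["disease_class_distribution"] = "disease_class_distribution.tsv"
            tab = top_class_enrichment(
                list(ranking.diseases), cmap, config.top_fraction, config.min_fold
            )
            tab.write_tsv(outdir / "disease_class_enrichment.tsv")
            manifest["outputs"]["disease_class_enrichment"] = "disease_class_enrichment.tsv"
            info["n_enriched_disease_classes"] = len(tab.table)
        if config.drug_classes:
            cmap = read_class_map(config.drug_classes)
            tab = top_class_enrichment(
                list(drugs.drugs), cmap, config.top_fraction, config.min_fold
            )
            tab.write_tsv(outdir / "drug_class_enrichment.tsv")
            manifest["outputs"]["drug_class_enrichment"] = "drug_class_enrichment.tsv"
            info["n_enriched_drug_classes"] = len(tab.table)
        done(**info)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current_stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
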