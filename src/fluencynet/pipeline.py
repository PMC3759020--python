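"""End-to-end orchestration of the fluency-network analysis.

``run_pipeline`` takes a :class:`PipelineConfig` and writes, per group: the
binary response matrix, the word correlation matrix, the PMFG network
(GraphML + edge list), the small-world metrics row, the random-graph null
summary, the bootstrap group comparison, the word impact table with its
group t-test, and a manifest recording configuration, seeds and versions so
a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import compare_impact, impact_scores, impact_table
from .correlation import CorrelationMatrix, word_correlations
from .fluency_data import (
    ResponseMatrix,
    build_response_matrix,
    load_fluency,
    restrict,
    select_wmcn_vocabulary,
    write_fluency,
)
from .netmetrics import summarize
from .nullmodels import ERSpec, bootstrap_partial, empirical_significance, simulate_er
from .pmfg import build_pmfg
from .synthetic import GroupProfile, builtin_profile, generate_pair, profile_from_yaml

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """Wraps an error with the pipeline stage in which it occurred."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full analysis run.

    Either ``input_path`` (long-format CSV/JSON with exactly two groups) or
    the two generator profiles must be supplied; when both are absent the
    shipped default profiles are used.
    """

    input_path: str | None = None
    profile_a: str | None = None  # builtin profile name or YAML path
    profile_b: str | None = None
    network_kind: str = "wmcn"  # or "smcn"
    min_subjects: int = 2
    er_realizations: int = 10_000
    bootstrap_subset_size: int = 40
    bootstrap_realizations: int = 10_000
    bootstrap_shared_subsets: bool = True
    reference_mode: str = "mean"  # or "single"
    reference_realizations: int = 100
    disconnection_policy: str = "largest_component"
    run_impact: bool = True
    seed: int = 0
    outdir: str = "fluencynet_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _resolve_profile(name_or_path: str) -> GroupProfile:
    p = Path(name_or_path)
    if p.suffix in (".yml", ".yaml") or p.exists():
        return profile_from_yaml(p)
    return builtin_profile(name_or_path)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - labelled re-raise
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %-12s %6.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


@_stage("load")
def _load_groups(cfg: PipelineConfig, outdir: Path):
    if cfg.input_path:
        datasets = load_fluency(cfg.input_path)
        if len(datasets) != 2:
            raise ValueError(
                f"pipeline expects exactly 2 groups, found {sorted(datasets)}"
            )
        a, b = (datasets[k] for k in sorted(datasets))
    else:
        prof_a = _resolve_profile(cfg.profile_a) if cfg.profile_a else builtin_profile("nh_like")
        prof_b = _resolve_profile(cfg.profile_b) if cfg.profile_b else builtin_profile("ci_like")
        a, b = generate_pair(prof_a, prof_b, seed=cfg.seed)
        write_fluency([a, b], outdir / "responses.csv")
    return a, b


@_stage("matricize")
def _matricize(cfg: PipelineConfig, a, b, outdir: Path):
    ma, mb = build_response_matrix(a), build_response_matrix(b)
    if cfg.network_kind == "wmcn":
        vocab = select_wmcn_vocabulary(ma, mb, min_subjects=cfg.min_subjects)
        ma, mb = restrict(ma, vocab), restrict(mb, vocab)
    elif cfg.network_kind != "smcn":
        raise ValueError(f"unknown network kind {cfg.network_kind!r}")
    for m in (ma, mb):
        m.to_csv(outdir / f"response_matrix_{m.group_label}.csv")
    return ma, mb


@_stage("correlate")
def _correlate(ma: ResponseMatrix, mb: ResponseMatrix, outdir: Path):
    ca, cb = word_correlations(ma), word_correlations(mb)
    ca.to_csv(outdir / f"correlations_{ma.group_label}.csv")
    cb.to_csv(outdir / f"correlations_{mb.group_label}.csv")
    return ca, cb


@_stage("pmfg")
def _networks(cfg: PipelineConfig, ca, cb, labels, outdir: Path):
    nets = []
    for c, label in zip((ca, cb), labels):
        net = build_pmfg(c, network_kind=cfg.network_kind.upper(), group_label=label)
        net.to_graphml(outdir / f"network_{label}.graphml")
        net.to_edgelist_csv(outdir / f"edges_{label}.csv")
        nets.append(net)
    return tuple(nets)


@_stage("metrics")
def _metrics(cfg: PipelineConfig, nets, labels, outdir: Path):
    rows = {}
    for net, label in zip(nets, labels):
        m = summarize(
            net,
            reference_realizations=cfg.reference_realizations,
            reference_mode=cfg.reference_mode,
            seed=cfg.seed,
        )
        rows[label] = m.to_row()
    pd.DataFrame(rows).to_csv(outdir / "metrics.csv", index_label="parameter")
    return rows


@_stage("null-er")
def _null_er(cfg: PipelineConfig, nets, labels, rows, outdir: Path):
    net = nets[0]
    spec = ERSpec.matched(
        n=net.n_nodes,
        n_edges=net.n_edges,
        realizations=cfg.er_realizations,
        seed=cfg.seed,
    )
    null = simulate_er(spec, disconnection_policy=cfg.disconnection_policy)
    summary = {
        "spec": {"n": spec.n, "p": spec.p, "realizations": spec.realizations},
        "disconnected_fraction": null.disconnected_fraction,
        "reference": null.table_row(),
        "observed": {},
    }
    for label in labels:
        obs = rows[label]
        summary["observed"][label] = {
            "L": {"value": obs["L"], "p": empirical_significance(obs["L"], null.l, "two")},
            "D": {"value": obs["D"], "p": empirical_significance(obs["D"], null.d, "two")},
            "CC": {"value": obs["CC"], "p": empirical_significance(obs["CC"], null.cc, "two")},
        }
    with open(outdir / "null_er.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
    pd.DataFrame(
        {"L": null.l.values, "D": null.d.values, "CC": null.cc.values}
    ).to_csv(outdir / "null_er_realizations.csv", index_label="realization")
    return summary


@_stage("bootstrap")
def _bootstrap(cfg: PipelineConfig, ca, cb, labels, outdir: Path):
    subset_size = cfg.bootstrap_subset_size
    if subset_size > ca.n_words:
        logger.warning(
            "bootstrap subset_size %d exceeds vocabulary %d; clamping",
            subset_size, ca.n_words,
        )
        subset_size = ca.n_words
    comparison = bootstrap_partial(
        ca,
        cb,
        subset_size=subset_size,
        realizations=cfg.bootstrap_realizations,
        seed=cfg.seed,
        shared_subsets=cfg.bootstrap_shared_subsets,
        group_labels=labels,
    )
    with open(outdir / "bootstrap.json", "w", encoding="utf-8") as fh:
        json.dump(comparison.summary_table(), fh, indent=1)
    frames = {
        (g, m): comparison.distributions[g][m].values
        for g in labels
        for m in ("L", "D", "CC")
    }
    pd.DataFrame({f"{g}_{m}": v for (g, m), v in frames.items()}).to_csv(
        outdir / "bootstrap_realizations.csv", index_label="realization"
    )
    return comparison


@_stage("impact")
def _impact(ca, cb, labels, outdir: Path):
    scores_a = impact_scores(ca, group_label=labels[0])
    scores_b = impact_scores(cb, group_label=labels[1])
    table = pd.concat([impact_table(scores_a), impact_table(scores_b)])
    table.to_csv(outdir / "impact.csv", index=False)
    test = compare_impact(scores_a, scores_b)
    result = {"t": test.t, "df": test.df, "p": test.p}
    with open(outdir / "impact_ttest.json", "w", encoding="utf-8") as fh:
        json.dump(result, fh, indent=1)
    return result


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    a, b = _load_groups(cfg, outdir)
    labels = (a.group_label, b.group_label)
    ma, mb = _matricize(cfg, a, b, outdir)
    ca, cb = _correlate(ma, mb, outdir)
    nets = _networks(cfg, ca, cb, labels, outdir)
    rows = _metrics(cfg, nets, labels, outdir)
    _null_er(cfg, nets, labels, rows, outdir)
    if cfg.network_kind == "wmcn":
        _bootstrap(cfg, ca, cb, labels, outdir)
        if cfg.run_impact:
            _impact(ca, cb, labels, outdir)
    manifest = {
        "package": "fluencynet",
        "version": __version__,
        "numpy": np.__version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "groups": list(labels),
        "n_words": {label: net.n_nodes for label, net in zip(labels, nets)},
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
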