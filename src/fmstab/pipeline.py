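"""End-to-end orchestration: normalise -> dissimilarities -> comparisons ->
per-OTU screen -> co-occurrence network, with deterministic outputs.

A :class:`RunConfig` names either input files (OTU table, metadata, tree) or
a simulation preset, plus the metrics, comparisons and testing parameters.
``run_pipeline`` writes plain-TSV result tables and a JSON manifest
sufficient to reproduce the bundle byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import CommunityTable, read_otu_table, to_proportions
from .comparisons import COMPARISONS, build_pair_design
from .diversity import alpha_diversity_table
from .metadata import read_metadata, check_pairing
from .network import CooccurrenceAnalysis
from .permutation import METRICS, run_comparison
from .screen import OtuStabilityScreen
from .simulate import preset_configs, simulate_community
from .trees import read_tree, check_tips

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_inputs"]

_log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "fmstab_out"
    preset: str | None = None            # simulation preset name, or None
    otu_table: str | None = None
    metadata: str | None = None
    tree: str | None = None
    metrics: tuple = METRICS
    comparisons: tuple = COMPARISONS
    n_perm: int = 999
    seed: int = 0
    q_threshold: float = 0.05
    n_bins: int = 4
    alpha: float = 0.05
    screen_comparison: str = "adult_within_individual_within_year"
    network_cohort: str = "adult"
    exclude_extra_pair: bool = False
    exclude_parasitic: bool = False

    def validate(self) -> None:
        bad = [c for c in self.comparisons if c not in COMPARISONS]
        if bad:
            raise ValueError(
                f"unknown comparison(s) {bad}; valid names: {list(COMPARISONS)}")
        bad = [m for m in self.metrics if m not in METRICS]
        if bad:
            raise ValueError(f"unknown metric(s) {bad}; valid: {list(METRICS)}")
        if self.preset is None and (self.otu_table is None or self.metadata is None):
            raise ValueError("provide either a preset or input file paths")
        if self.preset is not None and self.preset not in preset_configs():
            raise ValueError(
                f"unknown preset {self.preset!r}; "
                f"valid: {sorted(preset_configs())}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("metrics", "comparisons"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def load_inputs(config: RunConfig):
    """Load or simulate the (table, metadata, tree) triple of a run."""
    if config.preset is not None:
        cfg = preset_configs()[config.preset]
        table, metadata, tree, _ = simulate_community(cfg, seed=config.seed)
        return table, metadata, tree
    table = read_otu_table(config.otu_table)
    metadata = read_metadata(config.metadata)
    tree = read_tree(config.tree) if config.tree else None
    return table, metadata, tree


def validate_inputs(table: CommunityTable, metadata: pd.DataFrame, tree=None,
                    comparisons=COMPARISONS, metrics=METRICS) -> dict:
    """Cross-check table/metadata/tree consistency.

    Returns ``{"fatal": [...], "warnings": [...]}``; an empty report means a
    fully consistent input set.
    """
    report = {"fatal": [], "warnings": []}
    missing = [s for s in table.sample_ids if s not in metadata.index]
    if missing:
        report["fatal"].append(f"samples missing from metadata: {missing[:10]}")
    unused = [s for s in metadata.index if s not in set(table.sample_ids)]
    if unused:
        report["warnings"].append(
            f"metadata rows without table samples: {unused[:10]}")
    needs_tree = any(m.endswith("unifrac") for m in metrics)
    if needs_tree:
        if tree is None:
            report["fatal"].append("UniFrac requested but no tree provided")
        else:
            tips = {t.name for t in tree.tips()}
            absent = sorted(set(table.otu_ids) - tips)
            if absent:
                report["fatal"].append(
                    f"OTUs absent from tree (UniFrac requested): {absent[:10]}")
    elif tree is not None:
        tips = {t.name for t in tree.tips()}
        absent = sorted(set(table.otu_ids) - tips)
        if absent:
            report["warnings"].append(
                f"OTUs absent from tree (UniFrac not requested): {absent[:10]}")
    if not missing:
        meta = metadata.loc[table.sample_ids]
        for name in comparisons:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    build_pair_design(meta, name)
            except (ValueError, KeyError) as exc:
                report["warnings"].append(f"{name}: {exc}")
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns the manifest dictionary.

    Per-comparison failures are isolated into error rows of the results
    table; the manifest lists them so callers can exit non-zero.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = {}
    t0 = time.perf_counter()

    table, metadata, tree = load_inputs(config)
    check_pairing(table, metadata)
    meta = metadata.loc[table.sample_ids]
    stages["load"] = time.perf_counter() - t0

    # alpha diversity
    t = time.perf_counter()
    alpha = alpha_diversity_table(table)
    alpha.index.name = "sample_id"
    alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", float_format="%.6g")
    stages["alpha"] = time.perf_counter() - t

    # community comparisons
    t = time.perf_counter()
    ss = np.random.SeedSequence(config.seed)
    seeds = iter(int(s) for s in ss.generate_state(
        len(config.comparisons) * len(config.metrics) + 8) % (2 ** 31))
    rows, errors = [], []
    for comparison in config.comparisons:
        for metric in config.metrics:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = run_comparison(
                        table, meta, comparison, metric=metric, tree=tree,
                        n_perm=config.n_perm, seed=next(seeds),
                        exclude_extra_pair=config.exclude_extra_pair,
                        exclude_parasitic=config.exclude_parasitic)
                rows.append(res.to_dict())
            except (ValueError, KeyError) as exc:
                errors.append({"comparison": comparison, "metric": metric,
                               "error": str(exc)})
    results = pd.DataFrame(rows, columns=["comparison", "metric",
                                          "observed_diff", "ci_low", "ci_high",
                                          "p", "cliffs_d", "n_focal",
                                          "n_reference"])
    results.to_csv(outdir / "comparisons.tsv", sep="\t", index=False,
                   float_format="%.6g")
    stages["comparisons"] = time.perf_counter() - t

    # per-OTU screen
    t = time.perf_counter()
    screen_rows = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            screen = OtuStabilityScreen(
                table, meta, comparison=config.screen_comparison)
            screen_res = screen.fit(n_perm=config.n_perm, seed=next(seeds))
        screen_res.write_tsv(outdir / "otu_screen.tsv")
        screen_rows = len(screen_res.frame)
    except (ValueError, KeyError) as exc:
        errors.append({"comparison": config.screen_comparison,
                       "metric": "per_otu_bray_curtis", "error": str(exc)})
    stages["otu_screen"] = time.perf_counter() - t

    # co-occurrence network on one cohort
    t = time.perf_counter()
    cohort_mask = meta["cohort"] == config.network_cohort
    sub = table.subset_samples(list(meta.index[cohort_mask]))
    props = to_proportions(sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cooc = CooccurrenceAnalysis(props, n_bins=config.n_bins).fit(
            n_perm=min(config.n_perm, 1000), seed=next(seeds),
            alpha=config.alpha)
    cooc.network.edge_frame().to_csv(outdir / "network_edges.tsv", sep="\t",
                                     index=False, float_format="%.6g")
    nodes = pd.DataFrame({
        "otu_id": list(cooc.network.graph.nodes),
        "degree": [cooc.network.graph.degree(o)
                   for o in cooc.network.graph.nodes],
        "mean_abundance": props.data.mean(axis=1).reindex(
            list(cooc.network.graph.nodes)).to_numpy(),
    })
    nodes.to_csv(outdir / "network_nodes.tsv", sep="\t", index=False,
                 float_format="%.6g")
    stages["network"] = time.perf_counter() - t

    cfg_dict = asdict(config)
    cfg_dict["metrics"] = list(config.metrics)
    cfg_dict["comparisons"] = list(config.comparisons)
    manifest = {
        "package": "fmstab",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "n_samples": table.shape[1],
        "n_otus": table.shape[0],
        "n_comparison_rows": len(results),
        "n_screen_rows": screen_rows,
        "n_network_edges": cooc.network.n_edges,
        "errors": errors,
        "outputs": {},
    }
    for name, secs in stages.items():
        _log.info("stage %-12s %.2fs", name, secs)
    for name in ("alpha_diversity.tsv", "comparisons.tsv", "otu_screen.tsv",
                 "network_edges.tsv", "network_nodes.tsv"):
        path = outdir / name
        if path.exists():
            manifest["outputs"][name] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
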