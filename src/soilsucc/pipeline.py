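"""End-to-end orchestration: validate -> filter -> subsets -> summaries ->
torus associations -> network modularity -> RDA / hierarchical partitioning.

Both marker domains run through identical stages and are merged only in the
pooled association summary.  Every output TSV carries a commented provenance
header (config hash, seeds, grid layout); a JSON index lists all artifacts.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io, network, ordination, summary, torus
from ._util import percent


@dataclass
class RunConfig:
    counts: dict[str, str]              # domain -> counts TSV path
    metadata: str = ""
    env: str = ""
    out_dir: str = "results"
    orientation: str = "samples_as_rows"
    rare_threshold: float = summary.RARE_THRESHOLD
    subsets: tuple[str, ...] = ("all", "core", "dominant")
    layout: str = "2x2"
    alpha: float = 0.05
    exclude_identity: bool = True
    weight_mode: str = "summed_relative_abundance"
    resolution: float = 1.0
    network_seed: int = 42
    n_perm: int = 999
    ordination_seed: int = 7
    accumulation_permutations: int = 100
    accumulation_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "subsets" in raw:
            raw["subsets"] = tuple(raw["subsets"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, path: Path, header: list[str], index=False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_all(config: RunConfig, log=print) -> dict:
    """Run every stage; returns the machine-readable result index."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = [f"config_hash={chash}", f"layout={config.layout}",
              io.GRID_CONVENTION]
    index: dict = {"config_hash": chash, "files": {}, "metrics": {}}

    def record(name: str, path: Path) -> None:
        index["files"][name] = str(path)

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - abort names the stage
                raise StageError(name, exc) from exc
            log(f"[{name}] done in {time.perf_counter() - t0:.2f}s")
            return out
        return deco

    @stage("validate")
    def _inputs():
        meta = io.read_metadata(config.metadata)
        tables = {d: io.read_otu_table(p, orientation=config.orientation,
                                       domain_label=d)
                  for d, p in config.counts.items()}
        for t in tables.values():
            missing = set(t.sample_ids) - set(meta["sample_id"])
            if missing:
                raise io.ValidationError(
                    f"samples without metadata: {sorted(missing)[:5]}")
        return meta, tables

    meta, raw_tables = _inputs
    stage_of_sample = dict(zip(meta["sample_id"], meta["stage"]))

    @stage("filter")
    def filtered():
        return {d: summary.filter_rare(t, config.rare_threshold)
                for d, t in raw_tables.items()}

    @stage("summaries")
    def _summaries():
        for d, t in filtered.items():
            rich = summary.richness(t)
            kw = summary.kruskal_wallis(
                rich.to_numpy(), [stage_of_sample[s] for s in t.sample_ids],
                pairwise=True)
            rich_df = rich.reset_index().rename(columns={"index": "sample_id"})
            rich_df["stage"] = rich_df["sample_id"].map(stage_of_sample)
            _write(rich_df, out_dir / f"richness_{d}.tsv",
                   header + [f"kruskal_wallis_H={kw['H']:.6g}", f"p={kw['p']:.6g}"])
            record(f"richness_{d}", out_dir / f"richness_{d}.tsv")
            index["metrics"][f"kruskal_wallis_{d}"] = {"H": kw["H"], "p": kw["p"]}
            venn = summary.venn_partition(t, stage_of_sample)
            venn_df = pd.DataFrame(
                [{"stages": "+".join(sorted(k)), "n_otus": v}
                 for k, v in sorted(venn.region_counts.items(),
                                    key=lambda kv: (len(kv[0]), sorted(kv[0])))])
            _write(venn_df, out_dir / f"venn_{d}.tsv", header)
            record(f"venn_{d}", out_dir / f"venn_{d}.tsv")
            acc = summary.accumulation_curve(
                t, n_perm=config.accumulation_permutations,
                seed=config.accumulation_seed)
            _write(acc, out_dir / f"accumulation_{d}.tsv",
                   header + [f"seed={config.accumulation_seed}"])
            record(f"accumulation_{d}", out_dir / f"accumulation_{d}.tsv")
            stack = summary.composition_stack(t, stage_of_sample)
            _write(stack, out_dir / f"composition_{d}.tsv", header, index=True)
            record(f"composition_{d}", out_dir / f"composition_{d}.tsv")

    _ = _summaries

    @stage("torus")
    def torus_results():
        grid = torus.build_composite_grid(meta, layout=config.layout)
        results = {}
        for d, t in filtered.items():
            res = torus.torus_test(t, grid, alpha=config.alpha,
                                   exclude_identity=config.exclude_identity)
            _write(res, out_dir / f"associations_{d}.tsv", header)
            record(f"associations_{d}", out_dir / f"associations_{d}.tsv")
            results[d] = res
        summ = torus.summarize_associations(results)
        _write(summ.per_domain, out_dir / "association_summary.tsv", header)
        _write(summ.positive_by_habitat, out_dir / "association_by_habitat.tsv",
               header)
        record("association_summary", out_dir / "association_summary.tsv")
        record("association_by_habitat", out_dir / "association_by_habitat.tsv")
        index["metrics"]["associations"] = {
            r["domain"]: {"n_tested": int(r["n_tested"]),
                          "n_associated": int(r["n_associated"]),
                          "pct_associated": r["pct_associated"]}
            for _, r in summ.per_domain.iterrows()}
        index["metrics"]["n_associated_all_habitats"] = summ.n_associated_all_habitats
        return results

    @stage("network")
    def _network():
        for d, t in filtered.items():
            for sub in config.subsets:
                t_sub = summary.select_subset(t, summary.SubsetRule(sub))
                G = network.build_network(t_sub, stage_of_sample,
                                          weight_mode=config.weight_mode)
                part = network.detect_communities(
                    G, resolution=config.resolution, seed=config.network_seed)
                edges = network.edge_list(G)
                path = out_dir / f"network_{d}_{sub}.tsv"
                _write(edges, path,
                       header + [f"Q={part.Q:.6f}",
                                 f"n_communities={part.n_communities}",
                                 f"seed={config.network_seed}"])
                record(f"network_{d}_{sub}", path)
                index["metrics"][f"modularity_{d}_{sub}"] = part.Q

    _ = _network

    if config.env:
        @stage("ordination")
        def _ordination():
            env = io.read_env_table(config.env)
            for d, t in filtered.items():
                X = env.aligned_to(t)
                out = ordination.rda_analysis(t, X, n_perm=config.n_perm,
                                              seed=config.ordination_seed)
                res = out["ordination"]
                hp = out["hierarchical_partition"]
                table1 = pd.DataFrame({
                    "predictor": list(res.per_predictor_p),
                    "p_value": list(res.per_predictor_p.values()),
                })
                table1["significance"] = table1["p_value"].map(
                    ordination.significance_stars)
                _write(table1, out_dir / f"rda_pvalues_{d}.tsv",
                       header + [f"n_perm={config.n_perm}",
                                 f"seed={config.ordination_seed}",
                                 f"constrained_R2={res.constrained_R2:.6f}",
                                 f"adjusted_R2={res.adjusted_R2:.6f}",
                                 f"global_p={res.global_p:.6g}"])
                record(f"rda_pvalues_{d}", out_dir / f"rda_pvalues_{d}.tsv")
                _write(res.site_scores, out_dir / f"rda_sites_{d}.tsv", header,
                       index=True)
                record(f"rda_sites_{d}", out_dir / f"rda_sites_{d}.tsv")
                _write(hp.contributions, out_dir / f"hierpart_{d}.tsv",
                       header + [f"full_model_R2={hp.full_model_r2:.6f}",
                                 f"adjusted={hp.adjusted}"])
                record(f"hierpart_{d}", out_dir / f"hierpart_{d}.tsv")
                index["metrics"][f"rda_{d}"] = {
                    "constrained_R2": res.constrained_R2,
                    "adjusted_R2": res.adjusted_R2,
                    "constrained_pct": percent(res.constrained_R2, 1.0, 1),
                    "global_p": res.global_p,
                }

        _ = _ordination
    else:
        log("[ordination] skipped (no env table configured)")

    index_path = out_dir / "index.json"
    with open(index_path, "w", encoding="utf-8") as fh:
        json.dump(index, fh, indent=2, sort_keys=True)
    log(f"wrote {index_path}")
    return index
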