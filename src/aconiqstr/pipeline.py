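"""Config-driven orchestration of the QSTR / network / ranking stages.

A :class:`RunConfig` collects input paths, stage toggles and every tunable
with its module default; :func:`run_pipeline` executes the toggled stages
(fields -> pls -> ad, network, ranking) and writes one JSON report plus
per-stage CSVs. Every random draw is seeded from the config, so a fixed
config reproduces a byte-identical report (timestamps excluded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, ad, fields, network, pls, ranking
from .molecules import assign_gasteiger_charges, read_mol2, read_sdf
from .synthetic import load_fixtures


class ValidationError(ValueError):
    """Raised for inconsistent configuration before any stage runs."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    # inputs
    molecules: str | None = None          # SDF/MOL2 with aligned 3D structures
    activity: str | None = None           # CSV: id, pld50, is_test
    edges: str | None = None              # TSV edge list
    clusters: str | None = None           # CSV: cluster, protein
    ranking_table: str | None = None      # CSV: id, relevance, rank columns
    use_fixtures: bool = False            # score the bundled reference tables
    # stage toggles
    run_fields: bool = False
    run_qstr: bool = False
    run_ad: bool = False
    run_network: bool = False
    run_ranking: bool = False
    # tunables (module defaults)
    spacing: float = fields.DEFAULT_SPACING
    margin: float = fields.DEFAULT_MARGIN
    cap: float = fields.DEFAULT_CAP
    alpha: float = fields.DEFAULT_ALPHA
    filter_threshold: float = fields.DEFAULT_FILTER
    field_family: str = "comfa"           # comfa | comsia
    max_components: int = 10
    decile_fraction: float = 0.10
    decile_merge: str = "intersection"
    closeness_variant: str = "standard"
    min_cluster_size: int = network.MIN_SIZE
    min_density: float = network.MIN_DENSITY
    min_quality: float = network.MIN_QUALITY
    max_p_value: float = network.MAX_P
    n_perm: int = 999
    relevance_scheme: str = ranking.DEFAULT_SCHEME
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # output location is not part of the science
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        toggles = (self.run_fields, self.run_qstr, self.run_ad,
                   self.run_network, self.run_ranking)
        if not any(toggles):
            raise ValidationError("no stage enabled")
        if (self.run_fields or self.run_qstr) and not self.molecules and not self.use_fixtures:
            raise ValidationError("fields/qstr stages need a molecules input")
        if self.run_qstr and not self.activity and not self.use_fixtures:
            raise ValidationError("qstr stage needs an activity table")
        if self.run_ad and not self.run_qstr:
            raise ValidationError("ad stage requires the qstr stage")
        if self.run_network and not self.edges:
            raise ValidationError("network stage needs an edge list")
        if self.run_ranking and not self.ranking_table and not self.use_fixtures:
            raise ValidationError("ranking stage needs a ranking table or use_fixtures")


def _read_molecules(path: str):
    path = Path(path)
    reader = read_mol2 if path.suffix.lower() == ".mol2" else read_sdf
    return [assign_gasteiger_charges(m) for m in reader(path)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages and return (and write) the run report."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "timings_s": {},
    }

    block = None
    if config.run_fields:
        t0 = time.perf_counter()
        try:
            mols = _read_molecules(config.molecules)
            grid = fields.build_grid(mols, config.spacing, config.margin)
            if config.field_family == "comsia":
                block = fields.comsia_block(mols, grid, config.alpha)
            else:
                block = fields.comfa_block(mols, grid, cap=config.cap)
            block = fields.column_filter(block, config.filter_threshold)
            block.to_csv(out_dir / "field_block.csv")
            report["stages"]["fields"] = {
                "n_molecules": len(mols),
                "grid_dims": list(grid.dims),
                "n_columns": block.matrix.shape[1],
                "n_dropped": len(block.dropped_columns),
            }
        except Exception as exc:  # noqa: BLE001 - surface the failing stage
            raise StageError("fields", exc) from exc
        report["timings_s"]["fields"] = round(time.perf_counter() - t0, 3)

    model = dataset = None
    if config.run_qstr:
        t0 = time.perf_counter()
        try:
            import pandas as pd

            act = pd.read_csv(config.activity)
            if block is None:
                raise ValueError("qstr stage needs the fields stage (or a block CSV)")
            order = {str(i): k for k, i in enumerate(act["id"].astype(str))}
            idx = [order[str(m)] for m in block.molecule_ids]
            y = act["pld50"].to_numpy(float)[idx]
            is_test = act.get("is_test", pd.Series(np.zeros(len(act)))).to_numpy()[idx].astype(bool)
            if not is_test.any():
                is_test = pls.split_3to1(y, seed=config.seed)
            dataset = pls.QSTRDataset(block, y, is_test)
            model = pls.evaluate(dataset, config.max_components)
            pls.predictions_frame(model, dataset).to_csv(out_dir / "predictions.csv")
            report["stages"]["qstr"] = {
                "onc": model.stats["onc"], "q2": model.stats["q2"],
                "r2": model.stats["r2"], "see": model.stats["see"],
                "f": model.stats["f"],
                "r2_pred": model.stats.get("r2_pred"),
                "field_fractions": model.stats["field_fractions"],
                "is_good": model.is_good,
            }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("qstr", exc) from exc
        report["timings_s"]["qstr"] = round(time.perf_counter() - t0, 3)

    if config.run_ad:
        t0 = time.perf_counter()
        try:
            wr = ad.williams_report(model, dataset)
            wr.to_csv(out_dir / "ad_report.csv")
            report["stages"]["ad"] = ad.summary(wr)
        except Exception as exc:
            raise StageError("ad", exc) from exc
        report["timings_s"]["ad"] = round(time.perf_counter() - t0, 3)

    if config.run_network:
        t0 = time.perf_counter()
        try:
            g = network.read_edge_list(config.edges)
            table = network.centrality_table(g, config.closeness_variant)
            table.to_csv(out_dir / "centrality.csv")
            subnet = network.top_decile_overlap(table, config.decile_fraction,
                                               config.decile_merge)
            net_report = {
                "n_nodes": g.number_of_nodes(),
                "n_edges": g.number_of_edges(),
                "subnetwork": sorted(map(str, subnet)),
            }
            if config.clusters:
                import pandas as pd

                members = pd.read_csv(config.clusters)
                metrics = []
                for name, grp in members.groupby("cluster"):
                    metrics.append(network.cluster_metrics(
                        g, grp["protein"].astype(str), config.n_perm, config.seed))
                accepted = network.filter_clusters(
                    metrics, config.min_cluster_size, config.min_density,
                    config.min_quality, config.max_p_value)
                net_report["clusters"] = [m.as_dict() for m in metrics]
                net_report["accepted_clusters"] = [sorted(map(str, m.members))
                                                   for m in accepted]
            report["stages"]["network"] = net_report
        except Exception as exc:
            raise StageError("network", exc) from exc
        report["timings_s"]["network"] = round(time.perf_counter() - t0, 3)

    if config.run_ranking:
        t0 = time.perf_counter()
        try:
            if config.use_fixtures:
                fx = load_fixtures()
                table = fx.ranking
                exp_ranks = table.orderings["experimental"]
                graded = table.with_relevance(ranking.apply_scheme(
                    table.relevance, exp_ranks, config.relevance_scheme))
                names = ["ideal", "fit_2V7O", "fit_2VZ6"]
                n_items = table.n
            else:
                graded = ranking.read_ranking_csv(config.ranking_table)
                names = ["ideal", *graded.orderings]
                n_items = graded.n
            scores = ranking.score_table(graded, names)
            scores.to_csv(out_dir / "ndcg.csv")
            report["stages"]["ranking"] = {
                "n_items": n_items,
                "relevance_scheme": config.relevance_scheme if config.use_fixtures else "as_given",
                "ndcg": {name: round(float(scores.loc[name, "ndcg"]), 4)
                         for name in names},
            }
        except Exception as exc:
            raise StageError("ranking", exc) from exc
        report["timings_s"]["ranking"] = round(time.perf_counter() - t0, 3)

    stable = {k: v for k, v in report.items() if k != "timings_s"}
    with open(out_dir / "report.json", "w") as fh:
        json.dump(stable, fh, indent=2, sort_keys=True)
    return report
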