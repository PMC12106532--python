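"""End-to-end pipeline orchestration with one master seed.

Runs simulate -> preprocess -> cluster -> embed -> diffabund -> network ->
classify -> report in fixed order, each stochastic stage receiving a child
seed derived deterministically from the master seed, and writes a
provenance manifest (config hash, seeds, per-stage outputs with sha256
checksums, wall times).  Stage toggles skip a stage's outputs; stages
whose inputs were skipped are skipped too, with a warning in the log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import STAGES, sha256_file, stage_seeds
from .cluster import ClusteringConfig, SOMCluster, compute_frequencies
from .differential import clinical_correlations, stratify_by_age, test_subsets
from .embedding import event_embedding, subject_pca
from .network import CorrelationNetwork, export_network, layout
from .classify import ModelSpec, cohort_summary, comparator_models, fit_model
from .preprocess import PreprocessConfig, preprocess_cohort, read_cohort
from .simulate import build_default_scenario, build_validation_scenario, generate_cohort

logger = logging.getLogger("immunet.pipeline")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    outdir: str = "immunet_run"
    master_seed: int = 0
    scenario: str = "default"            # default | validation
    events_per_subject: int = 60_000
    downsample_to: int = 50_000
    asinh_cofactor: float = 5.0
    grid_rows: int = 10
    grid_cols: int = 10
    n_metaclusters: int = 47
    som_epochs: int = 20
    linkage: str = "average"
    tsne_events: int = 20_000
    tsne_perplexity: float = 30.0
    network_threshold: float = 0.6
    network_alpha: float = 0.05
    diff_alpha: float = 0.1
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in data.items() if k != "stages"})
        cfg.stages.update(data.get("stages", {}))
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _record(manifest, stage, outdir: Path, t0: float, seed: int, files: list[Path]):
    entry = {
        "seed": seed,
        "wall_time_s": round(time.perf_counter() - t0, 3),
        "outputs": {str(p.relative_to(outdir)): sha256_file(p) for p in files},
    }
    manifest["stages"][stage] = entry
    logger.info(
        "stage=%s seed=%d wall_time=%.2fs outputs=%d",
        stage, seed, entry["wall_time_s"], len(files),
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logging.getLogger("immunet").addHandler(fh)
    seeds = stage_seeds(config.master_seed)
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "seeds": seeds,
        "stages": {},
    }
    config.to_yaml(outdir / "config.yaml")
    on = config.stages

    pooled = freq = groups = clinical = model = None

    if on.get("simulate", True):
        t0 = time.perf_counter()
        builder = (
            build_validation_scenario
            if config.scenario == "validation"
            else build_default_scenario
        )
        scenario = builder(
            seed=seeds["simulate"], events_per_subject=config.events_per_subject
        )
        cohort_dir = generate_cohort(scenario, outdir / "cohort")
        files = sorted((outdir / "cohort").rglob("*.tsv")) + [
            outdir / "cohort" / "truth.json"
        ]
        _record(manifest, "simulate", outdir, t0, seeds["simulate"], files)
    else:
        cohort_dir = outdir / "cohort"

    if on.get("preprocess", True):
        t0 = time.perf_counter()
        matrices, clinical = read_cohort(
            cohort_dir / "events", cohort_dir / "clinical.tsv"
        )
        pcfg = PreprocessConfig(
            asinh_cofactor=config.asinh_cofactor,
            events_per_subject=config.downsample_to,
            seed=seeds["preprocess"],
        )
        pooled = preprocess_cohort(matrices, pcfg)
        _record(manifest, "preprocess", outdir, t0, seeds["preprocess"], [])

    if on.get("cluster", True) and pooled is not None:
        t0 = time.perf_counter()
        ccfg = ClusteringConfig(
            grid_rows=config.grid_rows,
            grid_cols=config.grid_cols,
            n_metaclusters=config.n_metaclusters,
            som_epochs=config.som_epochs,
            linkage=config.linkage,
            seed=seeds["cluster"],
        )
        som = SOMCluster(pooled, ccfg)
        model = som.fit()
        freq, groups = compute_frequencies(model)
        cdir = outdir / "cluster"
        cdir.mkdir(exist_ok=True)
        freq.to_csv(cdir / "frequencies.tsv", sep="\t")
        from .cluster import expression_heatmap

        heat = expression_heatmap(model, pooled)
        heat.to_csv(cdir / "heatmap.tsv", sep="\t")
        with open(cdir / "model.json", "w") as out:
            json.dump(
                {
                    "codebook": model.codebook.tolist(),
                    "node_to_metacluster": model.node_to_metacluster.tolist(),
                    "excluded_metaclusters": sorted(model.excluded_metaclusters),
                    "subset_labels": {str(k): v for k, v in model.subset_labels.items()},
                    "markers": model.markers,
                },
                out,
            )
        files = [cdir / "frequencies.tsv", cdir / "heatmap.tsv", cdir / "model.json"]
        _record(manifest, "cluster", outdir, t0, seeds["cluster"], files)

    if on.get("embed", True) and freq is not None:
        t0 = time.perf_counter()
        edir = outdir / "embed"
        edir.mkdir(exist_ok=True)
        pca = subject_pca(freq)
        pca.scores.to_csv(edir / "pca_scores.tsv", sep="\t")
        pca.loadings.to_csv(edir / "pca_loadings.tsv", sep="\t")
        pd.Series(pca.variance_explained, name="variance_fraction").to_csv(
            edir / "pca_variance.tsv", sep="\t"
        )
        rng = np.random.default_rng(seeds["embed"])
        take = min(config.tsne_events, len(pooled))
        idx = rng.choice(len(pooled), size=take, replace=False)
        sub = pooled.iloc[idx]
        emb = event_embedding(
            sub[model.markers].to_numpy(),
            seed=seeds["embed"],
            perplexity=config.tsne_perplexity,
        )
        coords = pd.DataFrame(emb.coordinates, columns=["tsne1", "tsne2"])
        coords["subject_id"] = sub["subject_id"].to_numpy()
        coords["group"] = sub["group"].to_numpy()
        coords.to_csv(edir / "tsne.tsv", sep="\t", index=False)
        files = sorted(edir.glob("*.tsv"))
        _record(manifest, "embed", outdir, t0, seeds["embed"], files)

    if on.get("diffabund", True) and freq is not None:
        t0 = time.perf_counter()
        ddir = outdir / "diffabund"
        ddir.mkdir(exist_ok=True)
        res = test_subsets(freq, groups, alpha=config.diff_alpha)
        res.table.to_csv(ddir / "differential.tsv", sep="\t")
        strata = stratify_by_age(freq, clinical, groups)
        for name, sres in strata.items():
            if sres is not None:
                sres.table.to_csv(ddir / f"differential_{name}.tsv", sep="\t")
        corr = clinical_correlations(freq, clinical)
        corr.to_csv(ddir / "clinical_correlations.tsv", sep="\t", index=False)
        files = sorted(ddir.glob("*.tsv"))
        _record(manifest, "diffabund", outdir, t0, seeds["diffabund"], files)

    if on.get("network", True) and freq is not None:
        t0 = time.perf_counter()
        ndir = outdir / "network"
        ndir.mkdir(exist_ok=True)
        nets = CorrelationNetwork(
            freq, groups, config.network_threshold, config.network_alpha
        ).fit()
        for group, net in nets.networks.items():
            export_network(net, nets.summaries[group], ndir, group)
            pos = layout(net, seed=seeds["network"])
            pd.DataFrame(
                [(node, xy[0], xy[1]) for node, xy in pos.items()],
                columns=["node", "x", "y"],
            ).to_csv(ndir / f"{group}_layout.tsv", sep="\t", index=False)
        with open(ndir / "contrast.json", "w") as out:
            json.dump(nets.contrast, out, indent=1)
        files = sorted(ndir.glob("*.tsv")) + sorted(ndir.glob("*.json"))
        _record(manifest, "network", outdir, t0, seeds["network"], files)

    if on.get("classify", True) and freq is not None:
        t0 = time.perf_counter()
        kdir = outdir / "classify"
        kdir.mkdir(exist_ok=True)
        metrics = {}
        # diagnostic models need the planted subset names only when columns
        # match; on clustered output use the top discriminating subsets
        diff = test_subsets(freq, groups, alpha=config.diff_alpha)
        enriched = (
            diff.table[diff.table["direction"] == "up"]
            .sort_values("cohens_d", ascending=False)
            .index.tolist()
        )
        four = (
            tuple(enriched[:4]) if len(enriched) >= 4 else tuple(freq.columns[:4])
        )
        specs = [
            ModelSpec("4-subset", four, "sepsis", True),
            ModelSpec("3-subset", four[:3], "sepsis", True),
        ]
        for spec in specs:
            try:
                res = fit_model(spec, freq, clinical)
                metrics[spec.name] = res.metrics.to_dict()
            except ValueError as err:
                logger.warning("model %s skipped: %s", spec.name, err)
        for outcome in ("picu_mortality", "severe_sepsis", "septic_shock"):
            try:
                res = fit_model(ModelSpec("3-subset", four[:3], outcome, True), freq, clinical)
                metrics[f"3-subset:{outcome}"] = res.metrics.to_dict()
            except ValueError as err:
                logger.warning("outcome %s skipped: %s", outcome, err)
            comp = comparator_models(clinical, outcome=outcome)
            for var, cm in comp.items():
                metrics[f"{var}:{outcome}"] = cm.to_dict()
        with open(kdir / "metrics.json", "w") as out:
            json.dump(metrics, out, indent=1)
        cohort_summary(clinical).to_csv(kdir / "cohort_summary.tsv", sep="\t", index=False)
        files = [kdir / "metrics.json", kdir / "cohort_summary.tsv"]
        _record(manifest, "classify", outdir, t0, seeds["classify"], files)

    if on.get("report", True):
        t0 = time.perf_counter()
        with open(outdir / "manifest.json", "w") as out:
            json.dump(manifest, out, indent=1, sort_keys=True)
        _record(manifest, "report", outdir, t0, seeds["report"], [outdir / "manifest.json"])
        with open(outdir / "manifest.json", "w") as out:
            json.dump(manifest, out, indent=1, sort_keys=True)
    return outdir
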