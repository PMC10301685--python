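"""Experiment orchestration and the command-line interface.

One declarative configuration names the dataset source (synthetic
parameters or input files), validation schemes, model variants, pathway
source (biological, plus optional size-matched random replicates), and a
master seed; ``run_experiment`` trains every (model, scheme, fold,
replicate) cell, scores it per cell line, and writes a results bundle:

    outdir/
      manifest.json          completed cells, config hash, seeds
      predictions/           one TSV per cell
      metrics/               per-cell-line metric tables
      comparisons/           percent improvement vs random collections
      aggregates.tsv         pooled mean ± SD per model x scheme

Completed cells are skipped on rerun, making a run resumable. Child seeds
derive from the master seed by stable hashing of the stage name and index.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import baselines, models_explicit, models_implicit
from .dataset import (
    UniformDataset,
    assemble_uniform_dataset,
    filter_low_variance,
    normalize_expression,
    read_fingerprints_tsv,
    read_omics_tsv,
    read_ppi_tsv,
    read_responses_tsv,
    read_targets_tsv,
    filter_targets,
)
from .evaluation import per_ccl_metrics, percent_improvement
from .nn import TrainConfig
from .pathways import PathwayCollection, randomize_collection, read_gmt
from .prediction import PredictionTable, read_predictions, write_predictions
from .splits import make_folds, validate_folds
from .synthetic_data import SyntheticConfig, generate, generate_raw, write_inputs

log = logging.getLogger(__name__)

PATHWAY_MODELS = (
    "pathdnn",
    "cds_gex",
    "cds_gex_cnv",
    "hidra_t",
    "hidra_fp",
    "pathdsp_t",
    "pathdsp_fp",
    "pathdsp_full",
)
ALL_MODELS = ("naive", "mlp_t", "mlp_fp", "rf_t", "rf_fp", *PATHWAY_MODELS)

PATHDSP_BLOCKS = {
    "pathdsp_t": ("GEx", "T"),
    "pathdsp_fp": ("GEx", "FP"),
    "pathdsp_full": ("GEx", "CNV", "Mut", "FP", "T"),
}


def derive_seed(master: int, stage: str, index: int = 0) -> int:
    """Stable child seed below 2^31 from (master, stage, index)."""
    digest = hashlib.sha256(f"{master}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one benchmark run."""

    outdir: str
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    input_dir: str | None = None  # read files instead of generating
    schemes: tuple[str, ...] = ("LCO",)
    models: tuple[str, ...] = ("naive", "pathdnn")
    folds: tuple[int, ...] = (0, 1, 2, 3, 4)
    n_random_replicates: int = 0
    n_permutations: int = 1000  # enrichment null size
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    master_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown model variant(s) {sorted(unknown)}")
        if self.n_random_replicates < 0:
            raise ValueError("replicate count must be >= 0")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("schemes", "models", "folds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def load_dataset_from_dir(indir: str | Path) -> UniformDataset:
    """Assemble a uniform dataset from a directory of input files."""
    indir = Path(indir)
    for name in ("gex_fpkm.tsv", "mut.tsv", "cnv.tsv", "targets.tsv",
                 "responses.tsv", "pathways.gmt"):
        if not (indir / name).exists():
            raise FileNotFoundError(indir / name)
    gex = filter_low_variance(
        normalize_expression(read_omics_tsv(indir / "gex_fpkm.tsv", "GEx"))
    )
    mut = read_omics_tsv(indir / "mut.tsv", "Mut")
    cnv = read_omics_tsv(indir / "cnv.tsv", "CNV")
    targets = filter_targets(read_targets_tsv(indir / "targets.tsv"))
    fp_path = indir / "fingerprints.tsv"
    fingerprints = read_fingerprints_tsv(fp_path) if fp_path.exists() else {}
    responses = read_responses_tsv(indir / "responses.tsv")
    collection = read_gmt(indir / "pathways.gmt")
    ppi_path = indir / "ppi.tsv"
    ppi = read_ppi_tsv(ppi_path) if ppi_path.exists() else None
    return assemble_uniform_dataset(
        gex, mut, cnv, targets, fingerprints, responses, collection, ppi
    )


class ModelRunner:
    """Trains one model variant on one fold, with optional pathway override."""

    def __init__(self, config: ExperimentConfig, dataset: UniformDataset):
        self.config = config
        self.dataset = dataset
        self._enrichment_cache: dict[tuple[str, tuple[str, ...]], dict] = {}

    def _train_config(self, seed: int) -> TrainConfig:
        return replace(TrainConfig(**self.config.train), seed=seed)

    def _enrichment(self, collection: PathwayCollection, blocks: tuple[str, ...], seed: int):
        key = (collection.name, blocks)
        if key not in self._enrichment_cache:
            self._enrichment_cache[key] = models_implicit.enrichment_features(
                self.dataset, collection, blocks,
                n_permutations=self.config.n_permutations, seed=seed,
            )
        return self._enrichment_cache[key]

    def run(
        self,
        model: str,
        scheme: str,
        fold: dict,
        collection: PathwayCollection,
        seed: int,
    ) -> PredictionTable:
        ds = self.dataset
        cfg = self._train_config(seed)
        if model == "naive":
            return baselines.naive_fit_predict(ds, fold, scheme)
        if model in ("rf_t", "rf_fp"):
            rep = "targets" if model.endswith("_t") else "fingerprint"
            return baselines.build_rf(rep, seed=seed).fit_predict(ds, fold)
        if model in ("mlp_t", "mlp_fp"):
            rep = "targets" if model.endswith("_t") else "fingerprint"
            net = baselines.build_mlp(ds, rep, cfg)
        elif model == "pathdnn":
            net = models_explicit.build_pathdnn(collection, ds.gene_order, cfg)
        elif model in ("cds_gex", "cds_gex_cnv"):
            mods = ("GEx",) if model == "cds_gex" else ("GEx", "CNV")
            net = models_explicit.build_cds(collection, ds.gene_order, mods, cfg)
        elif model in ("hidra_t", "hidra_fp"):
            rep = "targets" if model.endswith("_t") else "fingerprint"
            net = models_implicit.build_hidra(collection, ds.gene_order, rep, cfg)
        elif model in PATHDSP_BLOCKS:
            blocks = PATHDSP_BLOCKS[model]
            feats = self._enrichment(
                collection, blocks, derive_seed(self.config.master_seed, "enrichment")
            )
            net = models_implicit.build_pathdsp(feats, cfg)
        else:  # pragma: no cover - guarded by config validation
            raise ValueError(model)
        _, preds = models_explicit.train_regressor(net, ds, fold)
        return preds


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute every (model, scheme, fold, replicate) cell; return the bundle."""
    outdir = Path(config.outdir)
    for sub in ("predictions", "metrics", "comparisons"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    if manifest.get("config_hash") not in (None, config.config_hash()):
        raise ValueError("output directory holds results for a different config")
    manifest.setdefault("config_hash", config.config_hash())
    manifest.setdefault("config", asdict(config))
    manifest.setdefault("completed", {})
    manifest.setdefault("seeds", {})

    if config.input_dir:
        dataset = load_dataset_from_dir(config.input_dir)
    else:
        syn = SyntheticConfig(**{"seed": derive_seed(config.master_seed, "data"),
                                 **config.synthetic})
        dataset, _ = generate(syn)
    collection = dataset.collection
    runner = ModelRunner(config, dataset)

    replicates = {
        r: randomize_collection(
            collection, derive_seed(config.master_seed, "randomize", r)
        )
        for r in range(config.n_random_replicates)
    }

    rows = []
    pooled: dict[tuple[str, str, str], list[PredictionTable]] = {}
    for scheme in config.schemes:
        split_seed = derive_seed(config.master_seed, f"split:{scheme}")
        spec = make_folds(dataset, scheme, split_seed)
        validate_folds(spec, dataset)
        manifest["seeds"][f"split:{scheme}"] = split_seed
        spec.to_frame().to_csv(outdir / f"folds_{scheme}.tsv", sep="\t", index=False)
        for model in config.models:
            variants = [("bio", collection)]
            if model in PATHWAY_MODELS:
                variants += [(f"rand{r}", coll) for r, coll in replicates.items()]
            for tag, coll in variants:
                for k in config.folds:
                    cell = f"{model}:{scheme}:{k}:{tag}"
                    pred_path = outdir / "predictions" / f"{cell.replace(':', '_')}.tsv"
                    if cell in manifest["completed"] and pred_path.exists():
                        preds = read_predictions(pred_path)
                    else:
                        t0 = time.monotonic()
                        seed = derive_seed(config.master_seed, f"train:{cell}")
                        preds = runner.run(model, scheme, spec.folds[k], coll, seed)
                        write_predictions(preds, pred_path)
                        manifest["completed"][cell] = {
                            "seed": seed,
                            "elapsed_s": round(time.monotonic() - t0, 3),
                        }
                        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
                    pooled.setdefault((model, scheme, tag), []).append(preds)

    # pooled per-CCL metrics per (model, scheme, variant)
    summary: dict[str, dict] = {}
    for (model, scheme, tag), tables in pooled.items():
        metrics = per_ccl_metrics(pd.concat(tables, ignore_index=True))
        name = model if tag == "bio" else f"{model}_{tag}"
        metrics.table.to_csv(
            outdir / "metrics" / f"{name}_{scheme}_per_ccl.tsv", sep="\t"
        )
        for metric_name, row in metrics.aggregates.iterrows():
            rows.append(
                {
                    "model": name,
                    "scheme": scheme,
                    "metric": metric_name,
                    "mean": row["mean"],
                    "sd": row["sd"],
                    "n_defined": int(row["n_defined"]),
                }
            )
        summary[(model, scheme, tag)] = {
            m: metrics.aggregates.loc[m, "mean"] for m in ("scc", "rmse")
        }

    aggregates = pd.DataFrame(rows)
    aggregates.to_csv(outdir / "aggregates.tsv", sep="\t", index=False)

    # biological vs random-collection contrast
    improvements: dict[str, dict] = {}
    if config.n_random_replicates:
        for scheme in config.schemes:
            for model in config.models:
                if model not in PATHWAY_MODELS:
                    continue
                rand_keys = [
                    (model, scheme, f"rand{r}")
                    for r in range(config.n_random_replicates)
                ]
                if not all(k in summary for k in rand_keys):
                    continue
                real = summary[(model, scheme, "bio")]
                improvements[f"{model}:{scheme}"] = {
                    metric: percent_improvement(
                        real[metric], [summary[k][metric] for k in rand_keys], metric
                    )
                    for metric in ("scc", "rmse")
                } | {"n_replicates": config.n_random_replicates}
        (outdir / "comparisons" / "percent_improvement.json").write_text(
            json.dumps(improvements, indent=2, sort_keys=True)
        )

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "aggregates": aggregates,
        "percent_improvement": improvements,
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log per-stage progress.")
def cli(verbose: bool) -> None:
    """Benchmark pathway-informed drug-response models."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        stream=sys.stderr,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def _fail(exc: Exception) -> None:
    click.echo(f"error: {exc}", err=True)
    sys.exit(1)


@cli.command("generate")
@click.option("--out", required=True, type=click.Path())
@click.option("--seed", default=7, type=int)
@click.option("--n-celllines", default=120, type=int)
@click.option("--n-drugs", default=30, type=int)
@click.option("--n-genes", default=300, type=int)
@click.option("--n-pathways", default=20, type=int)
def generate_cmd(out, seed, n_celllines, n_drugs, n_genes, n_pathways):
    """Generate synthetic raw inputs into a directory."""
    try:
        raw, _ = generate_raw(
            SyntheticConfig(
                seed=seed,
                n_celllines=n_celllines,
                n_drugs=n_drugs,
                n_genes=n_genes,
                n_pathways=n_pathways,
            )
        )
        paths = write_inputs(raw, out)
    except Exception as exc:  # noqa: BLE001
        _fail(exc)
    click.echo(f"wrote {len(paths)} files to {out}")


@cli.command()
@click.option("--indir", required=True, type=click.Path())
@click.option("--out", required=True, type=click.Path())
def build(indir, out):
    """Assemble the uniform dataset; write the provenance report."""
    try:
        ds = load_dataset_from_dir(indir)
        Path(out).parent.mkdir(parents=True, exist_ok=True)
        Path(out).write_text(json.dumps(ds.provenance, indent=2, sort_keys=True))
    except Exception as exc:  # noqa: BLE001
        _fail(exc)
    click.echo(
        f"dataset: {len(ds.cellline_order)} cell lines, {len(ds.gene_order)} genes, "
        f"{len(ds.drugs)} drugs, {ds.collection.m} pathways"
    )


@cli.command()
@click.option("--indir", required=True, type=click.Path())
@click.option("--scheme", required=True, type=click.Choice(["LPO", "LCO", "LDO"]))
@click.option("--seed", default=0, type=int)
@click.option("--out", required=True, type=click.Path())
def split(indir, scheme, seed, out):
    """Write a validated five-fold assignment table."""
    try:
        ds = load_dataset_from_dir(indir)
        spec = make_folds(ds, scheme, seed)
        validate_folds(spec, ds)
        spec.to_frame().to_csv(out, sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        _fail(exc)
    click.echo(f"wrote folds for {scheme} (seed {seed}) to {out}")


@cli.command()
@click.option("--indir", required=True, type=click.Path())
@click.option("--scheme", required=True, type=click.Choice(["LPO", "LCO", "LDO"]))
@click.option("--fold", default=0, type=int)
@click.option("--model", "model_name", required=True, type=click.Choice(ALL_MODELS))
@click.option("--seed", default=0, type=int)
@click.option("--out", required=True, type=click.Path())
def train(indir, scheme, fold, model_name, seed, out):
    """Train one model on one fold; write its test predictions."""
    try:
        ds = load_dataset_from_dir(indir)
        spec = make_folds(ds, scheme, derive_seed(seed, f"split:{scheme}"))
        cfg = ExperimentConfig(outdir=".", models=(model_name,), master_seed=seed)
        preds = ModelRunner(cfg, ds).run(
            model_name, scheme, spec.folds[fold], ds.collection,
            derive_seed(seed, f"train:{model_name}:{scheme}:{fold}"),
        )
        write_predictions(preds, out)
    except Exception as exc:  # noqa: BLE001
        _fail(exc)
    click.echo(f"wrote {len(preds)} test predictions to {out}")


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path())
def experiment(config_path):
    """Run a full experiment from a YAML config."""
    try:
        cfg = ExperimentConfig.from_yaml(config_path)
        bundle = run_experiment(cfg)
    except Exception as exc:  # noqa: BLE001
        _fail(exc)
    click.echo(bundle["aggregates"].to_string(index=False))


@cli.command()
@click.option("--predictions", required=True, type=click.Path(exists=True))
@click.option("--out", type=click.Path())
def evaluate(predictions, out):
    """Per-cell-line metrics for one prediction table."""
    try:
        metrics = per_ccl_metrics(read_predictions(predictions))
    except Exception as exc:  # noqa: BLE001
        _fail(exc)
    if out:
        metrics.table.to_csv(out, sep="\t")
    click.echo(metrics.aggregates.to_string())


@cli.command()
@click.option("--outdir", required=True, type=click.Path(exists=True))
def report(outdir):
    """Print the pooled aggregate table of a completed run."""
    path = Path(outdir) / "aggregates.tsv"
    if not path.exists():
        _fail(FileNotFoundError(path))
    click.echo(pd.read_csv(path, sep="\t").to_string(index=False))
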