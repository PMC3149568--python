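"""Readers/writers for pipeline artifacts and the end-to-end driver.

All tables are TSV with a header row; expression matrices are stored
samples-in-rows with variable IDs as columns and sample IDs in the first
column. Labels live in a two-column companion file and are mapped to -1/+1
through an explicit, logged coding (e.g. ``AD=+1, control=-1``) — class
codings differ across studies, so they are declared, never inferred.
Missing values are a hard error: the supported inputs are normalized,
complete matrices.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import cluster_signature
from .datasets import (GroundTruth, LabeledDataset, SyntheticSpec,
                       generate_dataset, generate_genesets)
from .enrichment import enrich, read_annotation, read_gmt, write_gmt
from .model_selection import RegularizationGrid
from .signature import Signature, evaluate_test, final_model, mu_path

logger = logging.getLogger("l1l2sig")

__all__ = ["read_expression", "write_matrix", "write_labels",
           "write_signature", "read_signature", "write_truth",
           "PipelineConfig", "run_pipeline"]


def _map_labels(raw, label_map):
    raw = [str(v) for v in raw]
    if label_map:
        mapping = {str(k): int(v) for k, v in label_map.items()}
        unknown = sorted(set(raw) - set(mapping))
        if unknown:
            raise ValueError(
                f"unknown label values {unknown}; declared coding is "
                f"{mapping}")
        logger.info("label coding: %s", mapping)
        return np.array([mapping[v] for v in raw], dtype=float)
    try:
        y = np.array([float(v) for v in raw])
    except ValueError:
        raise ValueError(
            f"labels {sorted(set(raw))} are not numeric; declare a coding "
            f"such as {{'AD': 1, 'control': -1}}") from None
    return y


def read_expression(matrix_path, labels_path=None, orientation="samples",
                    label_map=None, sep="\t"):
    """Load a delimited expression matrix plus labels into a LabeledDataset.

    ``orientation`` declares what the file rows are ("samples" or
    "variables"); the in-memory matrix is always samples x variables.
    Labels come from a two-column companion file (sample_id, label) and are
    mapped to -1/+1 via ``label_map``. Missing cells, duplicate variable
    IDs and unknown label values are hard errors.
    """
    if orientation not in ("samples", "variables"):
        raise ValueError(
            f"orientation must be 'samples' or 'variables', got {orientation!r}")
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if orientation == "samples" and len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate variable IDs in {matrix_path}: {dupes}")
    df = pd.read_csv(matrix_path, sep=sep, index_col=0)
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().to_numpy())))
        raise ValueError(
            f"missing value at row {df.index[r]!r}, column {df.columns[c]!r} "
            f"in {matrix_path}")
    if orientation == "variables":
        df = df.T
    if df.columns.duplicated().any():
        dupes = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate variable IDs in {matrix_path}: {dupes}")
    if labels_path is None:
        raise ValueError("a labels file is required")
    lab = pd.read_csv(labels_path, sep=sep, index_col=0)
    if lab.shape[1] != 1:
        raise ValueError(
            f"labels file must have exactly one label column, got "
            f"{list(lab.columns)}")
    missing = [s for s in df.index if s not in lab.index]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    y = _map_labels(lab.loc[df.index].iloc[:, 0].tolist(), label_map)
    ds = LabeledDataset(df.to_numpy(dtype=float), y,
                        [str(c) for c in df.columns],
                        [str(i) for i in df.index])
    ds.column_means = ds.X.mean(axis=0)
    return ds


def write_matrix(dataset: LabeledDataset, path, sep="\t"):
    df = pd.DataFrame(dataset.X, index=pd.Index(dataset.sample_ids,
                                                name="sample_id"),
                      columns=dataset.variable_ids)
    df.to_csv(path, sep=sep, float_format="%.10g")


def write_labels(dataset: LabeledDataset, path, sep="\t"):
    pd.DataFrame({"label": dataset.y.astype(int)},
                 index=pd.Index(dataset.sample_ids, name="sample_id")
                 ).to_csv(path, sep=sep)


def write_truth(truth: GroundTruth, path, sep="\t"):
    df = pd.DataFrame({
        "variable_id": truth.variable_ids,
        "true_weight": truth.true_weights,
        "block": [truth.block_membership[v] for v in truth.variable_ids],
        "informative": [int(v in truth.informative_ids)
                        for v in truth.variable_ids],
    })
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def write_signature(sig: Signature, path, annotation=None, sep="\t"):
    """Signature TSV: variable_id, gene_symbol, entrez_id, frequency.

    Symbol/Entrez columns are filled from ``annotation`` when given, left
    blank otherwise. Metadata (mu level, threshold, source) is stored in
    leading ``#`` comment lines so a read round-trips the object.
    """
    rows = []
    for var, freq in sig.entries:
        symbol = entrez = ""
        if annotation is not None and var in annotation.mapping:
            symbol, entrez = annotation.mapping[var]
        rows.append((var, symbol, entrez, freq))
    with open(path, "w") as fh:
        fh.write(f"# mu_level: {sig.mu_level}\n")
        fh.write(f"# threshold: {sig.threshold}\n")
        fh.write(f"# source_dataset: {sig.source_dataset}\n")
        fh.write(sep.join(["variable_id", "gene_symbol", "entrez_id",
                           "frequency"]) + "\n")
        for var, symbol, entrez, freq in rows:
            fh.write(sep.join([str(var), str(symbol), str(entrez),
                               f"{freq:g}"]) + "\n")


def read_signature(path, sep="\t"):
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
        else:
            body.append(line)
    from io import StringIO
    df = pd.read_csv(StringIO("".join(body)), sep=sep, dtype=str)
    entries = [(row.variable_id, float(row.frequency))
               for row in df.itertuples(index=False)]
    return Signature(entries=entries,
                     mu_level=float(meta.get("mu_level", 1.0)),
                     threshold=float(meta.get("threshold", 40.0)),
                     source_dataset=meta.get("source_dataset", ""))


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, explicit and hashable.

    Either ``synthetic`` (a SyntheticSpec parameter dict) or both
    ``matrix``/``labels`` paths must be given. ``seed`` is mandatory: every
    stochastic stage (simulation, fold plans, k-means restarts) derives its
    randomness from it.
    """

    out_dir: str
    seed: int
    synthetic: dict | None = None
    matrix: str | None = None
    labels: str | None = None
    label_map: dict | None = None
    orientation: str = "samples"
    test_matrix: str | None = None
    test_labels: str | None = None
    K_outer: int = 10
    K_inner: int = 10
    mu_values: list = field(default_factory=lambda: [0.01, 0.1, 0.5, 1.0])
    threshold: float = 40.0
    alpha: float = 0.05
    min_genes: int = 3
    gmt: str | None = None
    annotation: str | None = None
    n_genesets: int = 20
    geneset_size: int = 15
    ista_tol: float = 1e-5
    ista_max_iter: int = 10_000

    def validate(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.synthetic is None and (self.matrix is None
                                       or self.labels is None):
            raise ValueError(
                "config must provide either a synthetic spec or both matrix "
                "and labels paths")
        for name in ("matrix", "labels", "test_matrix", "test_labels",
                     "gmt", "annotation"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self):
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig):
    """Run simulate/load -> mu-path training -> signature -> test ->
    cluster -> enrich and write every artifact plus a JSON run manifest.

    Stages are logged at their boundaries; a failure aborts with the stage
    name while earlier artifacts stay on disk. Re-running with the same
    config and seed reproduces byte-identical deterministic tables.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": config.config_hash(),
                "config": asdict(config), "stages": {}}
    stage = "load"
    try:
        truth = None
        collection = None
        if config.synthetic is not None:
            stage = "simulate"
            logger.info("stage %s", stage)
            spec = SyntheticSpec(**{**config.synthetic, "seed": config.seed})
            data, truth = generate_dataset(spec)
            write_matrix(data, out / "matrix.tsv")
            write_labels(data, out / "labels.tsv")
            write_truth(truth, out / "truth.tsv")
            collection = generate_genesets(
                truth, n_sets=config.n_genesets,
                set_size=config.geneset_size, seed=config.seed)
            write_gmt(collection, out / "genesets.gmt")
            manifest["stages"][stage] = {
                "n_samples": data.n_samples, "n_variables": data.n_variables}
        else:
            logger.info("stage %s", stage)
            data = read_expression(config.matrix, config.labels,
                                   orientation=config.orientation,
                                   label_map=config.label_map)
            manifest["stages"][stage] = {
                "n_samples": data.n_samples, "n_variables": data.n_variables}
        if config.gmt is not None:
            collection = read_gmt(config.gmt)
        annotation = (read_annotation(config.annotation)
                      if config.annotation else None)

        stage = "train"
        logger.info("stage %s", stage)
        grid = RegularizationGrid()
        path_result = mu_path(
            data, grid=grid, mu_values=config.mu_values,
            K_outer=config.K_outer, K_inner=config.K_inner,
            seed=config.seed, threshold=config.threshold,
            source_dataset="synthetic" if config.synthetic else
            str(config.matrix), tol=config.ista_tol,
            max_iter=config.ista_max_iter)
        cv_report = []
        for mu, sig, cv in path_result.entries:
            cv_report.append({
                "mu": mu, "mean_cv_error": cv.mean_error,
                "fold_errors": cv.fold_errors,
                "fold_params": [{"tau": t, "lambda": l}
                                for t, l in cv.fold_params],
                "fold_list_sizes": [len(s) for s in cv.fold_selected],
                "signature_size": len(sig),
            })
            for entry in cv_report[-1]["fold_params"]:
                logger.info("mu=%g tau*=%.4g lambda*=%.4g", mu,
                            entry["tau"], entry["lambda"])
        (out / "cv_report.json").write_text(
            json.dumps(cv_report, indent=2, sort_keys=True))
        manifest["stages"][stage] = {
            "mean_cv_error_at_mu1": cv_report[-1]["mean_cv_error"]}

        stage = "signature"
        logger.info("stage %s", stage)
        sig = path_result.reported
        cv1 = path_result.entries[-1][2]
        write_signature(sig, out / "signature.tsv", annotation=annotation)
        manifest["stages"][stage] = {"size": len(sig)}

        model = None
        if len(sig):
            model = final_model(data, sig, cv=cv1)
            (out / "model.json").write_text(json.dumps({
                "variable_ids": model.variable_ids,
                "beta": model.weights.beta.tolist(),
                "lambda": model.weights.lam,
                "column_means": model.column_means.tolist(),
            }, indent=2))

        if config.test_matrix is not None and model is not None:
            stage = "test"
            logger.info("stage %s", stage)
            test = read_expression(config.test_matrix, config.test_labels,
                                   orientation=config.orientation,
                                   label_map=config.label_map)
            counts = evaluate_test(model, test)
            (out / "test_confusion.json").write_text(
                json.dumps(counts.as_dict(), indent=2, sort_keys=True))
            manifest["stages"][stage] = counts.as_dict()

        if len(sig) >= 2:
            stage = "cluster"
            logger.info("stage %s", stage)
            k = max(1, min(path_result.minimal_list_size, len(sig)))
            assignment = cluster_signature(data, sig, k=k, seed=config.seed)
            assignment.to_csv(out / "clusters.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {"k": k}

        if collection is not None and len(sig):
            stage = "enrich"
            logger.info("stage %s", stage)
            genes = (annotation.map_ids(sig.variable_ids)
                     if annotation else set(sig.variable_ids))
            results, outside = enrich(genes, collection, alpha=config.alpha,
                                      min_genes=config.min_genes)
            df = pd.DataFrame([{
                "set": r.name, "category": r.category, "n_overlap": r.k,
                "p_value": f"{r.p_value:.6g}",
                "significant": int(r.significant),
                "enriched": int(r.enriched),
                "fdr_bh_nonstandard": f"{r.fdr_bh:.6g}",
                "overlap_genes": ",".join(r.overlap_genes),
            } for r in results])
            df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "n_scored": len(results),
                "n_enriched": int(sum(r.enriched for r in results)),
                "outside_universe": outside}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
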