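"""Published Alzheimer's-disease signatures bundled as worked examples.

Three two-class AD analyses run with the l1l2 double-optimization protocol
are distributed with the package as small TSV tables: the plasma
signaling-protein panel of Ray and colleagues ("protein") and the GEO
microarray series GSE1297 and GSE5281. Each table lists the selected
variables (probesets or protein spots) with their official gene symbol,
Entrez ID and cross-validation frequency score at mu = 1, plus the
corresponding KEGG over-representation statistics (overlap count and raw
hypergeometric p-value).

The expression matrices behind these signatures are external downloads and
are not shipped; the tables serve as fixtures for the stages that operate
on published results — frequency thresholding, gene-level intersection,
significant-versus-enriched flag logic, and the pathway overlap table.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .enrichment import AnnotationMap, EnrichmentResult
from .signature import Signature

__all__ = ["SIGNATURE_NAMES", "load_signature_table", "reference_signature",
           "reference_annotation", "load_kegg_table", "kegg_flagged_results"]

SIGNATURE_NAMES = ("protein", "gse1297", "gse5281")


def _read(fname):
    with resources.files("l1l2sig.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_signature_table(name):
    """Signature table (probeset_id, gene_symbol, entrez_id, frequency)."""
    if name not in SIGNATURE_NAMES:
        raise KeyError(f"unknown signature {name!r}; choose from "
                       f"{SIGNATURE_NAMES}")
    df = _read(f"ad_signature_{name}.tsv")
    df["frequency"] = df["frequency"].astype(float)
    return df


def reference_signature(name, threshold=40.0):
    """The published signature as a Signature object (inclusive threshold)."""
    df = load_signature_table(name)
    kept = df[df["frequency"] >= threshold]
    entries = sorted(zip(kept["probeset_id"], kept["frequency"]),
                     key=lambda kv: (-kv[1], kv[0]))
    return Signature(entries=[(v, float(f)) for v, f in entries],
                     mu_level=1.0, threshold=float(threshold),
                     source_dataset=name)


def reference_annotation(names=SIGNATURE_NAMES):
    """Probeset -> (symbol, Entrez) map pooled over the bundled tables."""
    mapping = {}
    for name in names:
        df = load_signature_table(name)
        for row in df.itertuples(index=False):
            mapping[row.probeset_id] = (row.gene_symbol, row.entrez_id)
    return AnnotationMap(mapping=mapping)


def load_kegg_table(name):
    """Published KEGG over-representation rows for one signature."""
    if name not in SIGNATURE_NAMES:
        raise KeyError(f"unknown signature {name!r}; choose from "
                       f"{SIGNATURE_NAMES}")
    df = _read(f"ad_kegg_{name}.tsv")
    df["n_overlap"] = df["n_overlap"].astype(int)
    df["p_value"] = df["p_value"].astype(float)
    return df


def kegg_flagged_results(name, alpha=0.05, min_genes=3):
    """EnrichmentResult list from the published (k, p) rows.

    The overlap counts and p-values are taken as published (the underlying
    KEGG release and reference universe are not recoverable); the
    significant / enriched flags are recomputed from the standard rule:
    significant when p <= alpha, enriched when additionally k >= min_genes.
    """
    df = load_kegg_table(name)
    out = []
    for row in df.itertuples(index=False):
        significant = row.p_value <= alpha
        out.append(EnrichmentResult(
            name=row.pathway, category=row.category, k=row.n_overlap,
            overlap_genes=(), p_value=row.p_value, significant=significant,
            enriched=significant and row.n_overlap >= min_genes))
    out.sort(key=lambda r: (r.p_value, r.name))
    return out
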