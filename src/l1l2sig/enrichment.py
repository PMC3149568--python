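"""Hypergeometric gene-set enrichment and multi-signature late integration.

Over-representation of a signature inside predefined gene sets (KEGG
pathways, GO terms, or synthetic collections) is scored by the upper-tail
hypergeometric test against a reference universe. Following the
WebGestalt-style convention, a set is *significant* when its raw p-value is
at or below alpha (0.05) and *enriched* when it is significant **and** at
least ``min_genes`` (3) signature genes fall in it — a significant set with
one or two genes is reported but not called enriched.

Late integration combines several datasets at the result level: gene-level
intersection of signatures (Entrez ID primary, symbol fallback) and a
pathway-overlap table marking where each set is enriched or
significant-only per signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

__all__ = ["GeneSetCollection", "EnrichmentResult", "AnnotationMap",
           "read_gmt", "write_gmt", "read_annotation", "hypergeom_p",
           "enrich", "intersect_signatures", "IntersectionResult",
           "overlap_table", "OverlapTable"]


@dataclass
class GeneSetCollection:
    """Named gene sets over a reference universe.

    ``sets`` maps name -> (category label, frozenset of member gene IDs).
    Members are restricted to the universe when scoring.
    """

    sets: dict
    universe: set

    def __post_init__(self):
        if not self.sets:
            raise ValueError("collection has no sets")
        self.universe = set(self.universe)

    def __len__(self):
        return len(self.sets)

    def restricted(self):
        """Members intersected with the universe, per set."""
        return {name: (cat, frozenset(m) & self.universe)
                for name, (cat, m) in self.sets.items()}


def read_gmt(path, universe=None):
    """Read a GMT file (name TAB description TAB member...).

    The description field is kept as the category label. ``universe``
    defaults to the union of all members ("collection as reference set").
    """
    sets = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{line_no}: GMT lines need name, description "
                    f"and at least one member")
            name, category = parts[0], parts[1]
            if name in sets:
                raise ValueError(f"{path}:{line_no}: duplicate set {name!r}")
            members = frozenset(g for g in parts[2:] if g)
            sets[name] = (category, members)
    if universe is None:
        universe = set().union(*(m for _, m in sets.values()))
    return GeneSetCollection(sets=sets, universe=set(universe))


def write_gmt(collection: GeneSetCollection, path):
    with open(path, "w") as fh:
        for name, (category, members) in collection.sets.items():
            fh.write("\t".join([name, category, *sorted(members)]) + "\n")


@dataclass
class AnnotationMap:
    """Probeset -> (gene symbol, Entrez ID) mapping.

    Gene identity for cross-platform comparison is the Entrez ID when
    present, the symbol otherwise.
    """

    mapping: dict  # probeset_id -> (symbol, entrez or None)

    def gene_key(self, probeset):
        symbol, entrez = self.mapping[probeset]
        return str(entrez) if entrez not in (None, "") else symbol

    def symbol_of_key(self, key):
        for symbol, entrez in self.mapping.values():
            if str(entrez) == key or symbol == key:
                return symbol
        return key

    def map_ids(self, probesets):
        """Gene keys for probesets; raises listing any unmapped ID."""
        missing = [p for p in probesets if p not in self.mapping]
        if missing:
            raise KeyError(f"unmapped probesets: {missing}")
        return {self.gene_key(p) for p in probesets}


def read_annotation(path):
    """Annotation TSV with columns probeset_id, gene_symbol, entrez_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probeset_id", "gene_symbol", "entrez_id"}
    if not required <= set(df.columns):
        raise ValueError(
            f"annotation file must have columns {sorted(required)}, "
            f"got {list(df.columns)}")
    mapping = {}
    for row in df.itertuples(index=False):
        mapping[row.probeset_id] = (row.gene_symbol, row.entrez_id)
    return AnnotationMap(mapping=mapping)


def hypergeom_p(N, K, n, k):
    """Upper-tail hypergeometric p-value P(X >= k).

    ``X`` counts the overlap when ``n`` genes are drawn without replacement
    from a universe of ``N`` genes of which ``K`` belong to the set. The
    tail is summed in log space for stability at extreme overlaps.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if not float(v).is_integer() or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N:
        raise ValueError(f"set size K={K} and draw size n={n} must not "
                         f"exceed the universe N={N}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    lo = max(k, K + n - N)
    hi = min(K, n)
    if lo > hi:
        return 0.0 if k > 0 else 1.0
    i = np.arange(lo, hi + 1)

    def lchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    logs = lchoose(K, i) + lchoose(N - K, n - i) - lchoose(N, n)
    return float(min(1.0, np.exp(logsumexp(logs))))


@dataclass
class EnrichmentResult:
    """One gene set scored against one signature."""

    name: str
    category: str
    k: int                  # overlap within the universe
    overlap_genes: tuple
    p_value: float
    significant: bool       # p <= alpha
    enriched: bool          # significant and k >= min_genes
    fdr_bh: float | None = None  # optional extra, not part of the flag logic


def enrich(signature_genes, collection: GeneSetCollection, alpha=0.05,
           min_genes=3):
    """Score every gene set with nonzero overlap against the signature.

    Genes outside the universe are excluded from all counts and reported in
    the returned ``outside_universe`` list. Results are sorted by p-value
    (ties by name) and carry both flags plus a Benjamini-Hochberg column as
    a clearly-optional extra (the flag logic uses raw p-values only).

    Returns ``(results, outside_universe)``.
    """
    genes = set(signature_genes)
    inside = genes & collection.universe
    outside = sorted(genes - collection.universe)
    if not inside:
        raise ValueError(
            "signature has no genes in the collection universe; check the "
            "annotation/ID space")
    N = len(collection.universe)
    n = len(inside)
    results = []
    for name, (category, members) in collection.restricted().items():
        overlap = inside & members
        if not overlap:
            continue
        K = len(members)
        k = len(overlap)
        p = hypergeom_p(N, K, n, k)
        significant = p <= alpha
        results.append(EnrichmentResult(
            name=name, category=category, k=k,
            overlap_genes=tuple(sorted(overlap)), p_value=p,
            significant=significant,
            enriched=significant and k >= min_genes))
    results.sort(key=lambda r: (r.p_value, r.name))
    if results:
        fdr = false_discovery_control([r.p_value for r in results])
        for r, q in zip(results, fdr):
            r.fdr_bh = float(q)
    return results, outside


@dataclass
class IntersectionResult:
    """Gene-level intersections across signatures (symbols reported)."""

    all_common: set
    pairwise: dict  # (name_i, name_j) -> set of symbols


def intersect_signatures(signatures, annotation: AnnotationMap | None = None):
    """Gene-level intersection of two or more signatures.

    ``signatures`` maps a name to an iterable of probeset/variable IDs.
    When an annotation is given, IDs are collapsed to genes first (Entrez
    primary, symbol fallback), so two probesets of the same gene count
    once; the reported sets use gene symbols. Without an annotation the raw
    IDs are intersected. The operation is commutative, associative and
    idempotent by construction.
    """
    if len(signatures) < 1:
        raise ValueError("need at least one signature")
    keyed = {}
    for name, ids in signatures.items():
        ids = list(ids)
        if annotation is not None:
            keyed[name] = annotation.map_ids(ids)
        else:
            keyed[name] = set(ids)

    def symbols(keys):
        if annotation is None:
            return set(keys)
        return {annotation.symbol_of_key(k) for k in keys}

    names = list(keyed)
    common = set.intersection(*keyed.values())
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = symbols(keyed[a] & keyed[b])
    return IntersectionResult(all_common=symbols(common), pairwise=pairwise)


@dataclass
class OverlapTable:
    """Pathway-level comparison of several signatures' enrichment runs."""

    table: pd.DataFrame       # rows: sets; columns: signatures; markers
    shared_all: list          # sets flagged (any level) in every signature
    shared_pairs: dict        # (sig_i, sig_j) -> sets flagged in both

    ENRICHED = "enriched"
    SIGNIFICANT = "significant"


def overlap_table(results):
    """Cross-signature pathway overlap, mirroring a filled/open marker table.

    ``results`` is a list of ``(signature_name, [EnrichmentResult, ...])``.
    Rows are the union of sets that are significant or enriched in at least
    one signature; each cell holds ``"enriched"``, ``"significant"`` or
    ``""``. Sets flagged in every signature and in each pair are summarized
    alongside.
    """
    if len(results) < 2:
        raise ValueError("overlap table needs >= 2 signatures")
    names = [name for name, _ in results]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate signature names: {names}")
    marks = {}
    categories = {}
    for name, res_list in results:
        for r in res_list:
            if r.enriched:
                marks[(r.name, name)] = OverlapTable.ENRICHED
            elif r.significant:
                marks[(r.name, name)] = OverlapTable.SIGNIFICANT
            categories.setdefault(r.name, r.category)
    rows = sorted({s for (s, _) in marks})
    table = pd.DataFrame("", index=pd.Index(rows, name="set"), columns=names)
    for (s, name), mark in marks.items():
        table.loc[s, name] = mark
    table.insert(0, "category", [categories.get(s, "") for s in rows])
    flagged = {name: {s for s in rows if table.loc[s, name] != ""}
               for name in names}
    shared_all = sorted(set.intersection(*flagged.values())) if names else []
    shared_pairs = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared_pairs[(a, b)] = sorted(flagged[a] & flagged[b])
    return OverlapTable(table=table, shared_all=shared_all,
                        shared_pairs=shared_pairs)
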