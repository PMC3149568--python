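"""Labeled expression containers and a synthetic two-class generator.

The generator emulates the statistical shape of small-cohort omics studies
(plasma-protein panels, brain microarray series): tens-to-hundreds of
samples, 10^2-10^4 variables, blocks of correlated variables, a small set of
class-discriminative variables and two roughly balanced classes. Every
downstream stage — selection, nested CV, clustering, enrichment — is
testable against the planted ground truth without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabeledDataset", "SyntheticSpec", "GroundTruth",
           "generate_dataset", "generate_genesets"]


@dataclass
class LabeledDataset:
    """A two-class samples x variables matrix with -1/+1 labels.

    ``X`` is stored as loaded (uncentered); ``centered()`` returns the
    zero-mean view together with the column means, which downstream code
    must reuse to center held-out data (training-mean centering is the only
    leakage-free choice).
    """

    X: np.ndarray
    y: np.ndarray
    variable_ids: list
    sample_ids: list
    column_means: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.variable_ids = list(self.variable_ids)
        self.sample_ids = list(self.sample_ids)
        n, d = self.X.shape
        if len(self.variable_ids) != d:
            raise ValueError(
                f"{len(self.variable_ids)} variable_ids for {d} columns")
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(set(self.variable_ids)) != d:
            raise ValueError("duplicate variable_ids")
        if not np.all(np.isfinite(self.X)):
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"variable {self.variable_ids[j]!r}")
        if self.y.shape[0] != n:
            raise ValueError(f"{self.y.shape[0]} labels for {n} samples")
        if not np.all(np.abs(self.y) == 1):
            bad = sorted(set(self.y) - {-1.0, 1.0})
            raise ValueError(f"labels must be -1/+1, found {bad}")

    @property
    def n_samples(self):
        return self.X.shape[0]

    @property
    def n_variables(self):
        return self.X.shape[1]

    def centered(self):
        """Return ``(X - column_means, column_means)``."""
        means = self.X.mean(axis=0)
        return self.X - means, means

    def subset(self, variable_ids):
        """Extract the sub-matrix of the given variables (order preserved).

        Raises ``KeyError`` listing any requested variable absent from the
        dataset — the guard used when applying a trained signature model to
        an independent test matrix.
        """
        index = {v: j for j, v in enumerate(self.variable_ids)}
        missing = [v for v in variable_ids if v not in index]
        if missing:
            raise KeyError(f"variables not in dataset: {missing}")
        cols = [index[v] for v in variable_ids]
        return LabeledDataset(self.X[:, cols], self.y,
                              [self.variable_ids[j] for j in cols],
                              self.sample_ids)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic two-class generator.

    The defaults are the benchmark design used throughout the test suite:
    100 samples, 500 variables, ten informative variables lying inside
    equicorrelated blocks (rho = 0.5, block size 5), a class mean shift of
    1.5 within-class standard deviations, and balanced classes.
    """

    n_samples: int = 100
    n_variables: int = 500
    block_size: int = 5
    n_blocks: int = 10
    within_block_corr: float = 0.5
    n_informative: int = 10
    effect_size: float = 1.5
    noise_sd: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def validate(self):
        for name in ("n_samples", "n_variables", "block_size", "n_blocks",
                     "n_informative"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.n_variables < 1:
            raise ValueError(f"n_variables must be >= 1, got {self.n_variables}")
        if not 0 <= self.within_block_corr < 1:
            raise ValueError(
                f"within_block_corr must be in [0, 1), got {self.within_block_corr}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0 < self.class_balance < 1:
            raise ValueError(
                f"class_balance must be in (0, 1), got {self.class_balance}")
        if self.n_informative > self.n_variables:
            raise ValueError(
                f"n_informative ({self.n_informative}) exceeds n_variables "
                f"({self.n_variables})")
        if self.block_size * self.n_blocks > self.n_variables:
            raise ValueError(
                f"block_size * n_blocks ({self.block_size * self.n_blocks}) "
                f"exceeds n_variables ({self.n_variables})")


@dataclass
class GroundTruth:
    """Planted signal of a synthetic dataset.

    ``informative_ids`` are exactly the variables with nonzero
    ``true_weights``; ``block_membership`` maps every variable to its
    correlated block (-1 for the independent-noise tail).
    """

    informative_ids: set
    true_weights: np.ndarray
    block_membership: dict
    variable_ids: list = field(default_factory=list)


def _var_ids(d):
    width = max(4, len(str(d)))
    return [f"V{j:0{width}d}" for j in range(d)]


def generate_dataset(spec: SyntheticSpec):
    """Draw one two-class dataset with correlated blocks and planted signal.

    Construction (all randomness from ``spec.seed``):

    1. labels: ``round(n * class_balance)`` positives, randomly placed;
    2. blocks tile the variable prefix; each block variable is
       ``sqrt(rho) * z_block + sqrt(1 - rho) * eps`` with a shared latent
       factor, giving exact pairwise population correlation ``rho``;
       variables beyond the blocks are independent standard normals;
    3. the field is scaled by ``noise_sd``; the first ``n_informative``
       variables get a class-conditional mean shift of
       ``+/- effect_size * noise_sd / 2``, i.e. a between-class mean
       difference of ``effect_size`` within-class standard deviations.

    Returns ``(LabeledDataset, GroundTruth)``; identical spec and seed give
    bitwise-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_variables
    rho, sigma = spec.within_block_corr, spec.noise_sd

    n_pos = int(round(n * spec.class_balance))
    if n_pos == 0 or n_pos == n:
        raise ValueError(
            f"class_balance {spec.class_balance} leaves a class empty at "
            f"n_samples={n}")
    y = -np.ones(n)
    y[rng.permutation(n)[:n_pos]] = 1.0

    X = rng.standard_normal((n, d))
    block_membership = {}
    ids = _var_ids(d)
    n_blocked = spec.block_size * spec.n_blocks
    for b in range(spec.n_blocks):
        z = rng.standard_normal(n)
        sl = slice(b * spec.block_size, (b + 1) * spec.block_size)
        X[:, sl] = np.sqrt(rho) * z[:, None] + np.sqrt(1 - rho) * X[:, sl]
    for j in range(d):
        block_membership[ids[j]] = j // spec.block_size if j < n_blocked else -1

    X *= sigma
    shift = spec.effect_size * sigma / 2.0
    informative = ids[: spec.n_informative]
    if spec.n_informative:
        X[:, : spec.n_informative] += np.where(y == 1, shift, -shift)[:, None]

    true_weights = np.zeros(d)
    true_weights[: spec.n_informative] = spec.effect_size
    truth = GroundTruth(
        informative_ids=set(informative),
        true_weights=true_weights,
        block_membership=block_membership,
        variable_ids=ids,
    )
    sample_ids = [f"S{i:04d}" for i in range(n)]
    return LabeledDataset(X, y, ids, sample_ids), truth


def generate_genesets(truth: GroundTruth, n_sets=20, set_size=15, seed=0):
    """Build a gene-set collection with one planted "causal" set.

    The causal set contains every informative variable padded up to
    ``set_size`` with random non-informative variables; the remaining
    ``n_sets - 1`` sets are drawn uniformly from the non-informative pool.
    The universe is the full variable list, so hypergeometric enrichment of
    a recovered signature against this collection has a known answer.
    """
    from .enrichment import GeneSetCollection

    if not truth.variable_ids:
        raise ValueError("GroundTruth carries no variable_ids")
    universe = list(truth.variable_ids)
    informative = sorted(truth.informative_ids)
    if set_size > len(universe):
        raise ValueError(
            f"set_size ({set_size}) exceeds n_variables ({len(universe)})")
    if set_size < len(informative):
        raise ValueError(
            f"set_size ({set_size}) smaller than the number of informative "
            f"variables ({len(informative)}): causal set cannot contain them all")
    if n_sets < 1:
        raise ValueError(f"n_sets must be >= 1, got {n_sets}")
    rng = np.random.default_rng(seed)
    noninf = [v for v in universe if v not in truth.informative_ids]
    pad = list(rng.choice(noninf, size=set_size - len(informative),
                          replace=False))
    sets = {"causal_set": ("synthetic", frozenset(informative + pad))}
    for i in range(n_sets - 1):
        members = rng.choice(noninf, size=set_size, replace=False)
        sets[f"random_set_{i:02d}"] = ("synthetic", frozenset(members))
    return GeneSetCollection(sets=sets, universe=set(universe))
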