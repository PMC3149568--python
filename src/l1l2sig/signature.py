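"""Frequency-thresholded signatures, the mu path, and held-out evaluation.

A *signature* is the list of variables whose frequency score — the share of
outer cross-validation folds selecting them — reaches a stability
threshold (40% by default; the comparison is inclusive). Signatures are
reported at the largest value of the correlation parameter (mu = 1), where
the elastic net admits whole groups of correlated variables; the list
obtained at the smallest mu (the "minimal list") fixes the cluster count
used when structuring the signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import LabeledDataset
from .linear_model import WeightVector, confusion, fit_rls, predict_labels
from .model_selection import CVResult, nested_cv

__all__ = ["Signature", "MuPathResult", "extract_signature", "mu_path",
           "final_model", "evaluate_test"]


@dataclass
class Signature:
    """Stable variables of a cross-validated selection, with frequencies.

    Entries are ``(variable_id, frequency_percent)`` ordered by descending
    frequency, ties by variable id, so the rendering is stable across runs.
    """

    entries: list
    mu_level: float
    threshold: float
    source_dataset: str = ""

    @property
    def variable_ids(self):
        return [v for v, _ in self.entries]

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_frame(self):
        return pd.DataFrame(self.entries,
                            columns=["variable_id", "frequency"])


@dataclass
class MuPathResult:
    """Signatures along the mu path of one dataset."""

    entries: list  # list of (mu, Signature, CVResult), mu ascending

    @property
    def reported(self):
        """The signature at the largest mu (mu = 1), the one reported."""
        return self.entries[-1][1]

    @property
    def minimal_list_size(self):
        """Size of the signature at the smallest mu; sets the k-means k."""
        return len(self.entries[0][1])

    def signature_at(self, mu):
        for m, sig, _ in self.entries:
            if m == mu:
                return sig
        raise KeyError(f"no signature at mu={mu}")


def extract_signature(cv: CVResult, threshold=40.0, source_dataset=""):
    """Keep the variables whose frequency is >= ``threshold`` percent.

    The comparison is inclusive — variables sitting exactly at the
    threshold are retained. An empty signature is legal and returned as
    such; downstream model fitting rejects it explicitly.
    """
    if not 0 < threshold <= 100:
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    freqs = cv.frequencies
    kept = freqs[freqs >= threshold]
    entries = sorted(kept.items(), key=lambda kv: (-kv[1], kv[0]))
    return Signature(entries=[(v, float(f)) for v, f in entries],
                     mu_level=cv.mu, threshold=float(threshold),
                     source_dataset=source_dataset)


def mu_path(data: LabeledDataset, grid=None, mu_values=(0.01, 0.1, 0.5, 1.0),
            K_outer=10, K_inner=10, seed=0, threshold=40.0,
            source_dataset="", **cv_kwargs):
    """One nested CV + signature extraction per mu level.

    ``mu_values`` must be sorted ascending with 1 as the largest value: the
    reported signature is the mu = 1 entry and the smallest-mu signature
    provides the minimal-list size for clustering. Each mu level reuses the
    same seed, so fold plans are identical across the path and frequency
    differences reflect the penalty alone.
    """
    mu_values = list(mu_values)
    if not mu_values:
        raise ValueError("mu_values must be nonempty")
    if any(b <= a for a, b in zip(mu_values, mu_values[1:])):
        raise ValueError(f"mu_values must be sorted ascending, got {mu_values}")
    if mu_values[-1] != 1.0:
        raise ValueError(
            f"largest mu must be 1 (the reported signature level), "
            f"got {mu_values[-1]}")
    entries = []
    for mu in mu_values:
        cv = nested_cv(data, grid=grid, mu=mu, K_outer=K_outer,
                       K_inner=K_inner, seed=seed, **cv_kwargs)
        sig = extract_signature(cv, threshold=threshold,
                                source_dataset=source_dataset)
        entries.append((mu, sig, cv))
    return MuPathResult(entries=entries)


@dataclass
class SignatureModel:
    """A signature together with its fitted RLS classifier and centering."""

    weights: WeightVector
    signature: Signature
    column_means: np.ndarray

    @property
    def variable_ids(self):
        return self.weights.variable_ids


def final_model(data: LabeledDataset, sig: Signature, lam=None,
                cv: CVResult | None = None):
    """RLS refit on the full training set restricted to the signature.

    ``lam`` defaults to the median of the per-fold lambda* values of ``cv``
    (a robust summary of what the inner loops considered appropriate).
    The returned model stores the training column means of the signature
    sub-matrix; held-out evaluation must reuse them.
    """
    if len(sig) == 0:
        raise ValueError("empty signature: no variables reached the "
                         "frequency threshold")
    if lam is None:
        if cv is None:
            raise ValueError("provide lam explicitly or a CVResult to take "
                             "the median fold lambda* from")
        lam = float(np.median([l for _, l in cv.fold_params]))
    sub = data.subset(sig.variable_ids)
    Xc, means = sub.centered()
    beta = fit_rls(Xc, sub.y, lam)
    weights = WeightVector(beta=beta, mu=sig.mu_level, lam=float(lam),
                           variable_ids=sig.variable_ids)
    return SignatureModel(weights=weights, signature=sig, column_means=means)


def evaluate_test(model: SignatureModel, test: LabeledDataset):
    """Apply a trained signature model to an independent test set.

    The test phase extracts the sub-matrix of the signature variables,
    centers it with the *training* means stored in the model, classifies by
    the sign of the linear score and returns the TP/FN/FP/TN decomposition
    (+1 = diseased is the positive class). Multi-group test sets are
    expected to arrive already binarized (e.g. AD versus not-AD, or MCI
    conversion as the positive status).
    """
    sub = test.subset(model.variable_ids)
    pred = predict_labels(model.weights.beta, sub.X, model.column_means)
    return confusion(pred, sub.y)
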