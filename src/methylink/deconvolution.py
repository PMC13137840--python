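"""Bulk expression deconvolution as non-negative weighted sums of
cell-type signature profiles.

For each bulk sample b the weights solve min_w ||b - S w||_2 subject to
w >= 0 on the gene intersection of bulk and signature, and proportions are
w / sum(w).  Proportions are therefore invariant to rescaling of the bulk
vector.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

__all__ = ["NNLSDeconvolver", "estimate_proportions", "batch_deconvolve"]


class NNLSDeconvolver(BaseEstimator):
    """Non-negative least-squares cell-type deconvolver.

    fit() takes the signature matrix (genes x cell types, non-negative,
    unique gene labels, no all-zero column); transform() maps bulk
    expression (genes x samples, or a single Series) to a cell_types x
    samples proportion DataFrame.  Residual L2 norms of the NNLS fits are
    stored in ``residuals_`` after transform.
    """

    def fit(self, signature: pd.DataFrame, y=None):
        sig = signature.astype(float)
        if sig.index.duplicated().any():
            raise ValueError("duplicate gene labels in signature")
        if (sig.to_numpy() < 0).any():
            raise ValueError("signature must be non-negative")
        if (sig.to_numpy().sum(axis=0) == 0).any():
            bad = sig.columns[sig.to_numpy().sum(axis=0) == 0][0]
            raise ValueError(f"all-zero signature column {bad!r}")
        self.signature_ = sig
        self.cell_types_ = list(sig.columns)
        return self

    def transform(self, bulk) -> pd.DataFrame:
        if not hasattr(self, "signature_"):
            raise RuntimeError("fit the signature first")
        if isinstance(bulk, pd.Series):
            bulk = bulk.to_frame(name=bulk.name or "sample")
        bulk = bulk.astype(float)
        if (bulk.to_numpy() < 0).any():
            raise ValueError("bulk expression must be non-negative")
        genes = self.signature_.index.intersection(bulk.index)
        n_types = len(self.cell_types_)
        if len(genes) == 0:
            raise ValueError("no genes shared between bulk and signature")
        if len(genes) < n_types:
            raise ValueError(
                f"only {len(genes)} shared genes for {n_types} cell types"
            )
        S = self.signature_.loc[genes].to_numpy()
        props = np.empty((n_types, bulk.shape[1]))
        resid = np.empty(bulk.shape[1])
        for j, col in enumerate(bulk.columns):
            b = bulk.loc[genes, col].to_numpy()
            w, rnorm = nnls(S, b)
            total = w.sum()
            if total == 0:
                warnings.warn(
                    f"sample {col!r}: all-zero weights; returning uniform "
                    f"proportions",
                    stacklevel=2,
                )
                props[:, j] = 1.0 / n_types
            else:
                props[:, j] = w / total
            resid[j] = rnorm
        self.residuals_ = pd.Series(resid, index=bulk.columns, name="residual")
        return pd.DataFrame(props, index=self.cell_types_, columns=bulk.columns)

    def fit_transform(self, signature: pd.DataFrame, bulk) -> pd.DataFrame:
        return self.fit(signature).transform(bulk)


def estimate_proportions(bulk_vector: pd.Series, signature: pd.DataFrame):
    """Proportions and residual for a single bulk sample."""
    model = NNLSDeconvolver().fit(signature)
    props = model.transform(bulk_vector)
    return props.iloc[:, 0], float(model.residuals_.iloc[0])


def batch_deconvolve(bulk_matrix: pd.DataFrame, signature: pd.DataFrame):
    """Independent per-sample NNLS solves; returns (proportions, residuals)."""
    model = NNLSDeconvolver().fit(signature)
    props = model.transform(bulk_matrix)
    return props, model.residuals_
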