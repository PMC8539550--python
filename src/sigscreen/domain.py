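"""Leverage (hat-value) applicability domain and Williams-plot data.

The applicability domain of the descriptor-based model is defined in the
classical QSPR way: for a training descriptor matrix X (n rows, p = 6
columns) augmented with an intercept column, the leverage of a query row x
is h = x~^T (X~^T X~)^-1 x~.  Rows with h above the critical value

    h* = 3 (p + 1) / n

are outside the domain and receive no prediction.  The Williams plot pairs
each record's standardized residual with its leverage, flagging response
outliers (|r| > 3) and structurally extrapolated points (h > h*)
separately.

Note on n: the critical value is 0.120 for n = 175 training points and
0.122 for n = 172 (175 minus the three admissible outliers); which n the
threshold should use is a modelling choice, so ``fit_ad`` takes an
explicit override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ADModel",
    "fit_ad",
    "leverage",
    "leverages",
    "critical_leverage",
    "williams_data",
]


def critical_leverage(p: int, n: int) -> float:
    """h* = 3(p+1)/n."""
    if n <= p + 1:
        raise ValueError("need more training rows than descriptors + 1")
    return 3.0 * (p + 1) / n


@dataclass(frozen=True)
class ADModel:
    """Leverage machinery fitted on a training descriptor matrix."""

    moments: np.ndarray      # (p+1, p+1) inverse cross-product, intercept first
    p: int
    n: int
    h_star: float
    columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.moments, dtype=float)
        if m.shape != (self.p + 1, self.p + 1):
            raise ValueError("moments must be (p+1) x (p+1)")
        m = m.copy(); m.setflags(write=False)
        object.__setattr__(self, "moments", m)


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.hstack([np.ones((X.shape[0], 1)), X])


def fit_ad(descriptor_matrix, n_for_hstar: int | None = None) -> ADModel:
    """Fit the leverage model on training descriptors.

    Parameters
    ----------
    descriptor_matrix : (n, p) array or DataFrame
    n_for_hstar : optional int
        n used in the critical-value formula; defaults to the number of
        rows.  Lets the caller reproduce a threshold quoted for a reduced
        training pool (e.g. after outlier removal).

    Raises a ``ValueError`` naming the collinear columns if the augmented
    matrix is rank deficient.
    """
    cols: tuple[str, ...] = ()
    if isinstance(descriptor_matrix, pd.DataFrame):
        cols = tuple(descriptor_matrix.columns)
        X = descriptor_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(descriptor_matrix, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more training rows than descriptors + 1")
    Xa = _augment(X)
    G = Xa.T @ Xa
    rank = np.linalg.matrix_rank(Xa)
    if rank < p + 1:
        # name the offending columns via near-null singular vectors
        _, s, vt = np.linalg.svd(Xa)
        null = vt[rank:]
        involved = sorted(set(np.where(np.any(np.abs(null) > 1e-8, axis=0))[0]))
        names = [("intercept" if j == 0 else (cols[j - 1] if cols else f"col{j-1}")) for j in involved]
        raise ValueError(f"descriptor matrix is rank deficient; collinear columns: {names}")
    moments = np.linalg.inv(G)
    return ADModel(
        moments=moments,
        p=p,
        n=n,
        h_star=critical_leverage(p, n_for_hstar if n_for_hstar is not None else n),
        columns=cols,
    )


def leverages(ad: ADModel, X) -> np.ndarray:
    """Hat values of one or more descriptor rows."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    Xa = _augment(X)
    return np.einsum("ij,jk,ik->i", Xa, ad.moments, Xa)


def leverage(ad: ADModel, x) -> float:
    """Hat value of a single descriptor row."""
    from .descriptors import DescriptorVector

    if isinstance(x, DescriptorVector):
        x = x.as_array()
    return float(leverages(ad, np.atleast_2d(np.asarray(x, dtype=float)))[0])


def williams_data(ad: ADModel, dataset, predictions) -> pd.DataFrame:
    """Standardized residuals vs leverages with outlier/domain flags.

    ``dataset`` is an (X, y) pair (or anything :func:`~sigscreen.ensemble`
    accepts); ``predictions`` are model means aligned with the records.
    The residual sd used for standardization is computed over all records.
    """
    from .ensemble import _as_xy

    X, y, _ = _as_xy(dataset)
    pred = np.asarray(predictions, dtype=float)
    if pred.shape != y.shape:
        raise ValueError("predictions must align with the dataset records")
    resid = pred - y
    sd = float(resid.std())
    std_resid = resid / sd if sd > 0 else np.zeros_like(resid)
    h = leverages(ad, X)
    return pd.DataFrame(
        {
            "residual": resid,
            "std_residual": std_resid,
            "leverage": h,
            "outlier": np.abs(std_resid) > 3.0,
            "out_of_domain": h > ad.h_star,
        }
    )
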