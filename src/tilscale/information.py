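"""Entropy, mutual information and information coverage.

Information coverage (IC) quantifies how much of a full scale's
information a condensed scale retains:

    IC = MI(condensed, full) / H(full)

with plug-in (empirical frequency) estimators and base-2 logarithms.
IC is base-invariant and lies in [0, 1]; for a deterministic coarsening
f of the full score, MI(f(X), X) = H(f(X)) so IC = H(condensed)/H(full)
exactly.  Half-integer medians count as their own categories.  The
plug-in estimator carries small-sample bias; it is reported as-is (no
bias correction), with n attached to each result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["entropy", "mutual_information", "information_coverage", "ICResult"]


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[~np.isnan(v)]


def entropy(values) -> float:
    """Plug-in empirical entropy in bits, -sum p log2 p."""
    v = _clean(values)
    if v.size == 0:
        raise ValueError("entropy of an empty sample is undefined")
    _, counts = np.unique(v, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(x, y) -> float:
    """Plug-in mutual information of paired discrete observations, in bits."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise ValueError("mutual information of an empty sample is undefined")
    joint = pd.crosstab(x, y).to_numpy(dtype=float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())


@dataclass(frozen=True)
class ICResult:
    """Information coverage of a condensed scale for one pairing."""

    pairing: str  # e.g. "daily", "max", "median"
    mi: float
    entropy_full: float
    ic: float
    n: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.reason is None


def information_coverage(full, condensed, pairing: str = "daily") -> ICResult:
    """IC = MI(condensed, full) / H(full) on complete pairs.

    A zero-entropy full scale (constant scores) makes IC undefined and
    is reported as such rather than raising.
    """
    f = np.asarray(full, dtype=float)
    c = np.asarray(condensed, dtype=float)
    keep = ~(np.isnan(f) | np.isnan(c))
    f, c = f[keep], c[keep]
    if f.size == 0:
        return ICResult(pairing, np.nan, np.nan, np.nan, 0, reason="no complete pairs")
    h = entropy(f)
    if h == 0:
        return ICResult(
            pairing, 0.0, 0.0, np.nan, f.size, reason="zero-entropy full scale"
        )
    mi = mutual_information(c, f)
    return ICResult(pairing, mi, h, mi / h, f.size)
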