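"""Genomic relationship matrix (VanRaden method 1).

G = Z Z' / (2 * sum_j p_j (1 - p_j)), with Z the dosage matrix column-centered
at twice the observed allele frequency.  Missing dosages are mean-imputed
(i.e. contribute zero after centering); monomorphic markers are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING

__all__ = ["GRM", "compute_grm"]


@dataclass
class GRM:
    ids: list[str]
    matrix: np.ndarray
    n_markers: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM dimension does not match id list")

    def align(self, ids) -> np.ndarray:
        """Submatrix in the order of ``ids``."""
        index = {a: i for i, a in enumerate(self.ids)}
        idx = [index[a] for a in ids]
        return self.matrix[np.ix_(idx, idx)]


def compute_grm(dosages: np.ndarray, ids: list[str] | None = None) -> GRM:
    """VanRaden method-1 GRM from a (animals x markers) dosage matrix.

    Allele frequencies are estimated from the observed (non-missing) calls;
    markers monomorphic after imputation are dropped.
    """
    D = np.asarray(dosages, dtype=float)
    if D.ndim != 2:
        raise ValueError("dosage matrix must be 2-D (animals x markers)")
    miss = D == MISSING
    Dm = np.where(miss, np.nan, D)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(Dm, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all markers are monomorphic; GRM undefined")
    p = p[poly]
    Z = Dm[:, poly] - 2.0 * p
    Z[~np.isfinite(Z)] = 0.0  # mean imputation of missing dosages
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = Z @ Z.T / denom
    if ids is None:
        ids = [f"I{i}" for i in range(D.shape[0])]
    return GRM(ids=list(ids), matrix=G, n_markers=int(poly.sum()))
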