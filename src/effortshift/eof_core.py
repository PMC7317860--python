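"""Empirical orthogonal function (EOF) decomposition of anomaly matrices.

EOFs are the eigenvectors of the space x space covariance matrix of a
(complete) time x space anomaly matrix X.  With columns centred over time,

    C = X'X / (T - 1),      C e_i = lambda_i e_i,

the spatial modes e_i are orthonormal, the principal components are
PC_i = X e_i, and lambda_i measures the variance carried by mode i, so
100 * lambda_i / sum(lambda) is its explained-variance fraction.  Because
field variance is not spatially uniform, the per-grid-point "local"
explained variance of mode i among the leading k_max modes is

    LC_ji = e_ji^2 lambda_i / sum_{k<=k_max} lambda_k e_jk^2,

which sums to 1 over i at every grid point j where the denominator is
positive.

Sign convention: each mode is flipped so that its largest-magnitude spatial
loading is positive (with the PC flipped along), making correlations
between PCs of different fields reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AnomalyMatrix, CorrelationResult
from .cog_analysis import correlate
from .errors import AlignmentError, InsufficientDataError, MissingDataError

log = logging.getLogger(__name__)


@dataclass
class EOFDecomposition:
    """Full EOF decomposition of an anomaly matrix.

    ``eigenvalues`` and ``var_frac`` cover every mode; ``modes`` (space x k)
    and ``pcs`` (time x k) hold the leading ``k`` modes requested.
    """

    eigenvalues: np.ndarray  # descending, variance units
    var_frac: np.ndarray  # %, sums to 100 over all modes
    modes: np.ndarray  # (space, k), orthonormal columns
    pcs: np.ndarray  # (time, k)
    time_index: pd.PeriodIndex
    space_index: list
    column_means: np.ndarray  # means removed before the decomposition
    lc_map: np.ndarray | None = None  # (space, k_max)
    k_max: int | None = None

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def pc_series(self, mode: int) -> pd.Series:
        """1-based principal-component series of one mode."""
        if not 1 <= mode <= self.n_modes:
            raise ValueError(f"mode {mode} not available (have {self.n_modes})")
        return pd.Series(self.pcs[:, mode - 1], index=self.time_index, name=f"PC{mode}")


def eof(matrix: AnomalyMatrix, n_modes: int | None = None, k_max_lc: int = 3) -> EOFDecomposition:
    """Eigendecompose the space x space anomaly covariance.

    The matrix must be complete (DINEOF-fill first) with at least three time
    steps.  Columns are centred over time; the covariance uses the n-1
    denominator.  Rank-deficient matrices yield trailing zero eigenvalues.
    """
    X = np.asarray(matrix.values, dtype=float)
    if np.isnan(X).any():
        raise MissingDataError(
            "anomaly matrix has missing entries; reconstruct with DINEOF first"
        )
    n_t, n_s = X.shape
    if n_t < 3:
        raise InsufficientDataError("EOF needs >= 3 time steps")

    mu = X.mean(axis=0)
    Xc = X - mu
    C = Xc.T @ Xc / (n_t - 1)
    lam, vec = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    lam = np.where(lam > 0, lam, 0.0)  # clip numerical negatives

    k = n_s if n_modes is None else min(n_modes, n_s)
    modes = vec[:, :k].copy()
    # deterministic sign: largest-|loading| entry of each mode positive
    for i in range(k):
        j = int(np.argmax(np.abs(modes[:, i])))
        if modes[j, i] < 0:
            modes[:, i] = -modes[:, i]
    pcs = Xc @ modes

    total = lam.sum()
    var_frac = 100.0 * lam / total if total > 0 else np.zeros_like(lam)
    decomp = EOFDecomposition(
        eigenvalues=lam,
        var_frac=var_frac,
        modes=modes,
        pcs=pcs,
        time_index=matrix.time_index,
        space_index=list(matrix.space_index),
        column_means=mu,
    )
    if k_max_lc:
        decomp.k_max = min(k_max_lc, k)
        decomp.lc_map = local_explained_variance(decomp, decomp.k_max)
    return decomp


def local_explained_variance(decomp: EOFDecomposition, k_max: int) -> np.ndarray:
    """Per-grid-point variance share of each leading mode (space x k_max).

    Rows sum to 1; grid points where the leading-mode reconstruction carries
    no variance are NaN (logged).
    """
    if not 1 <= k_max <= decomp.n_modes:
        raise ValueError(f"k_max must be in 1..{decomp.n_modes}")
    e2l = decomp.modes[:, :k_max] ** 2 * decomp.eigenvalues[:k_max]
    denom = e2l.sum(axis=1)
    lc = np.full_like(e2l, np.nan)
    ok = denom > 0
    lc[ok] = e2l[ok] / denom[ok, None]
    if (~ok).any():
        log.warning(
            "local_explained_variance: %d grid point(s) with zero reconstructed variance",
            int((~ok).sum()),
        )
    return lc


def pc_correlation(
    decomp_a: EOFDecomposition,
    decomp_b: EOFDecomposition,
    mode_a: int = 1,
    mode_b: int = 1,
) -> CorrelationResult:
    """Pearson correlation between two fields' PC series (1-based modes)."""
    if not decomp_a.time_index.equals(decomp_b.time_index):
        raise AlignmentError("PC series do not share the same quarterly time index")
    return correlate(decomp_a.pc_series(mode_a), decomp_b.pc_series(mode_b))
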