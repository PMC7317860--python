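"""DINEOF: iterative truncated-SVD reconstruction of missing matrix entries.

Data Interpolating EOF fills gaps in a time x space anomaly matrix by
alternating between a rank-k truncated SVD of the current matrix and
replacement of the missing entries with their rank-k reconstruction, for
k = 1..k_max.  The optimal rank is chosen by cross-validation: a random
subset of *observed* entries is hidden, treated as missing during the
iterations, and the k minimising the RMSE at those entries wins (ties go
to the smaller k).  Observed entries are never altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import AnomalyMatrix
from .errors import EmptyInputError, InsufficientDataError

log = logging.getLogger(__name__)


@dataclass
class DineofResult:
    """Gap-filled matrix plus the cross-validation record of the rank search."""

    filled: AnomalyMatrix
    k_opt: int | None  # None when the input had no missing entries
    cv_rmse: dict  # candidate k -> validation RMSE
    n_iterations: dict  # candidate k -> iterations used
    converged: bool
    delta_history: dict = field(default_factory=dict)  # k -> per-iteration RMS change
    validation_entries: np.ndarray | None = None  # (n_val, 2) row/col indices
    seed: int | None = None


def select_reconstructable(
    matrix: AnomalyMatrix, max_missing_frac: float = 0.25
) -> AnomalyMatrix:
    """Keep spatial columns with strictly less missing data than the threshold.

    The default mirrors the usual selection rule: series with < 25% missing
    time steps are reconstructable; a column at exactly the threshold is
    dropped (strict inequality).
    """
    if not 0 < max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in (0, 1]")
    frac = matrix.missing_fraction
    keep = frac < max_missing_frac
    n_keep = int(keep.sum())
    log.info(
        "select_reconstructable: retained %d / %d columns (< %.0f%% missing)",
        n_keep,
        matrix.n_space,
        100 * max_missing_frac,
    )
    if n_keep == 0:
        raise EmptyInputError(
            f"no column has < {100 * max_missing_frac:.0f}% missing data"
        )
    space = [cell for cell, k in zip(matrix.space_index, keep) if k]
    return AnomalyMatrix(
        matrix.values[:, keep].copy(),
        matrix.time_index,
        space,
        matrix.climatology[:, keep].copy(),
    )


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x)))) if x.size else 0.0


def _truncated(X: np.ndarray, k: int) -> np.ndarray:
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return (U[:, :k] * s[:k]) @ Vt[:k]


def dineof_fill(
    matrix: AnomalyMatrix,
    k_max: int | None = None,
    cv_frac: float = 0.05,
    tol: float = 1e-5,
    max_iter: int = 500,
    seed: int = 0,
    min_val_entries: int = 30,
) -> DineofResult:
    """Reconstruct missing entries by cross-validated truncated-SVD iteration.

    Parameters follow the standard recipe: ``cv_frac`` of the observed
    entries (at least ``min_val_entries``) are hidden for rank selection;
    iteration at each k stops when the relative RMS change at the replaced
    entries falls below ``tol`` or after ``max_iter`` sweeps.  Ranks that do
    not converge are flagged and excluded from selection.  The final fill
    re-runs at the selected rank with the validation entries restored as
    observed.
    """
    X = np.asarray(matrix.values, dtype=float)
    miss = np.isnan(X)
    n_t, n_s = X.shape

    def _result_matrix(vals: np.ndarray) -> AnomalyMatrix:
        return AnomalyMatrix(
            vals, matrix.time_index, list(matrix.space_index), matrix.climatology.copy()
        )

    if not miss.any():
        return DineofResult(
            filled=_result_matrix(X.copy()),
            k_opt=None,
            cv_rmse={},
            n_iterations={},
            converged=True,
            seed=seed,
        )
    if miss.all(axis=0).any():
        raise InsufficientDataError(
            "a column is 100% missing; run select_reconstructable first"
        )

    hard_max = min(n_t, n_s) - 1
    if k_max is None:
        k_max = hard_max
    elif k_max > hard_max:
        log.warning("dineof_fill: k_max clipped from %d to %d", k_max, hard_max)
        k_max = hard_max
    if k_max < 1:
        raise ValueError("k_max must be >= 1")

    rng = np.random.default_rng(seed)
    obs = np.argwhere(~miss)
    n_val = max(int(round(cv_frac * len(obs))), min_val_entries)
    n_val = min(n_val, max(len(obs) - 1, 1))
    val_rows = obs[rng.choice(len(obs), size=n_val, replace=False)]
    val = np.zeros_like(miss)
    val[val_rows[:, 0], val_rows[:, 1]] = True

    # the input is an anomaly matrix, centred per cell and quarter-of-year by
    # construction, so no further mean removal is applied: subtracting
    # subset-dependent column means would raise the rank of an exactly
    # low-rank field by one and bias the rank selection
    train_obs = ~miss & ~val
    Xc = X.copy()
    replaced = miss | val
    Xc[replaced] = 0.0
    scale = _rms(Xc[train_obs]) + 1e-300
    truth_val = X[val]

    cv_rmse: dict[int, float] = {}
    n_iterations: dict[int, int] = {}
    delta_history: dict[int, list] = {}
    converged_k: dict[int, bool] = {}
    fills: dict[int, np.ndarray] = {}

    current = Xc.copy()
    for k in range(1, k_max + 1):
        deltas = []
        ok = False
        for it in range(1, max_iter + 1):
            recon = _truncated(current, k)
            delta = _rms(recon[replaced] - current[replaced]) / scale
            current[replaced] = recon[replaced]
            deltas.append(delta)
            if delta < tol:
                ok = True
                break
        cv_rmse[k] = _rms(current[val] - truth_val)
        n_iterations[k] = len(deltas)
        delta_history[k] = deltas
        converged_k[k] = ok
        fills[k] = current[miss].copy()
        if not ok:
            log.warning("dineof_fill: k=%d did not converge in %d iterations", k, max_iter)

    usable = [k for k in cv_rmse if converged_k[k]]
    if not usable:
        raise InsufficientDataError(
            f"DINEOF failed to converge for any k in 1..{k_max}"
        )
    # validation errors within the convergence tolerance of the minimum are
    # indistinguishable; parsimony picks the smallest such rank
    best = min(cv_rmse[k] for k in usable)
    k_opt = min(k for k in usable if cv_rmse[k] <= best + tol * scale)

    # final pass: validation entries restored as observed, only true gaps free
    final = X.copy()
    final[miss] = fills[k_opt]
    final_scale = _rms(final[~miss]) + 1e-300
    for it in range(1, max_iter + 1):
        recon = _truncated(final, k_opt)
        delta = _rms(recon[miss] - final[miss]) / final_scale
        final[miss] = recon[miss]
        if delta < tol:
            break

    out = X.copy()
    out[miss] = final[miss]
    return DineofResult(
        filled=_result_matrix(out),
        k_opt=k_opt,
        cv_rmse=cv_rmse,
        n_iterations=n_iterations,
        converged=all(converged_k.values()),
        delta_history=delta_history,
        validation_entries=val_rows,
        seed=seed,
    )
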