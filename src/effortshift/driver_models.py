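"""Random-forest attribution of effort to management, agreement, technology
and climate drivers.

Two regression forests relate quarterly effort (fishing hours) and the
leading effort-anomaly principal component to seven predictors: the
regional SSTA mean, the calendar quarter (4-level factor), the % of catch
taken on FADs (technology proxy), binary TAC and time-area-closure flags,
and the number of fisheries partnership agreements (SFPAs) and of vessels
they admit.  Influence is measured by out-of-bag permutation importance
(%IncMSE) and directionality by partial dependence curves; collinearity is
screened beforehand with generalized variance inflation factors (GVIF),
where factors enter as groups of indicator columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import InsufficientDataError, SchemaError

log = logging.getLogger(__name__)

#: the seven predictors of the attribution models
PREDICTORS = ("ssta", "quarter", "fad_prop", "tac", "closure", "agr_num", "agr_vessel")

RESPONSES = {"effort": "response_effort", "pc1": "response_pc1"}

GVIF_FLAG_THRESHOLD = 6.0


def design_matrix(
    table: pd.DataFrame, predictors: tuple | list = PREDICTORS
) -> tuple[pd.DataFrame, dict]:
    """Dummy-code the predictor columns.

    The 4-level ``quarter`` factor becomes three indicators (level 1 is the
    reference); all other predictors are single numeric columns.  Returns
    the design and a mapping predictor -> list of design columns (the
    grouping used by GVIF and by grouped permutation).
    """
    missing = [c for c in predictors if c not in table.columns]
    if missing:
        raise SchemaError(f"covariate table missing column(s): {', '.join(missing)}")
    cols = {}
    groups: dict[str, list] = {}
    for name in predictors:
        if name == "quarter":
            q = table["quarter"].astype(int)
            group = []
            for level in (2, 3, 4):
                col = f"quarter_{level}"
                cols[col] = (q == level).astype(float)
                group.append(col)
            groups[name] = group
        else:
            cols[name] = table[name].astype(float)
            groups[name] = [name]
    return pd.DataFrame(cols, index=table.index), groups


@dataclass
class GVIFReport:
    """Generalized variance inflation factors per predictor group."""

    table: pd.DataFrame  # index=predictor; columns gvif, df, gvif_scaled, flagged
    threshold: float = GVIF_FLAG_THRESHOLD

    @property
    def flagged(self) -> list:
        return list(self.table.index[self.table["flagged"]])


def gvif(
    table: pd.DataFrame,
    predictors: tuple | list | None = None,
    threshold: float = GVIF_FLAG_THRESHOLD,
) -> GVIFReport:
    """Fox-Monette GVIF of each (possibly multi-column) predictor group.

    With R the correlation matrix of all dummy-coded predictor columns,
    GVIF_j = det(R_jj) det(R_(-j)(-j)) / det(R).  Single-column groups
    reduce to the classical VIF = 1 / (1 - R_j^2).  A singular R yields an
    infinite GVIF (perfect collinearity).

    ``predictors`` defaults to the seven model predictors when the table
    carries them, otherwise to every non-response column.
    """
    if predictors is None:
        if all(c in table.columns for c in PREDICTORS):
            predictors = PREDICTORS
        else:
            predictors = [c for c in table.columns if c not in RESPONSES.values()]
    X, groups = design_matrix(table, predictors)
    n, p = X.shape
    if n < p + 2:
        raise InsufficientDataError(f"GVIF needs >= {p + 2} rows, got {n}")
    sd = X.std(axis=0, ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        raise InsufficientDataError(f"constant predictor column(s): {', '.join(const)}")

    R = np.corrcoef(X.to_numpy(), rowvar=False)
    colpos = {c: i for i, c in enumerate(X.columns)}

    def _logdet(idx: list[int]) -> float:
        sign, ld = np.linalg.slogdet(R[np.ix_(idx, idx)])
        return ld if sign > 0 else -np.inf

    ld_all = _logdet(list(range(p)))
    rows = {}
    for name, cols in groups.items():
        j = [colpos[c] for c in cols]
        rest = [i for i in range(p) if i not in j]
        if ld_all == -np.inf:
            g = np.inf
        else:
            ld_j = _logdet(j)
            ld_rest = _logdet(rest) if rest else 0.0
            g = float(np.exp(ld_j + ld_rest - ld_all))
            g = max(g, 1.0)  # numerical floor; GVIF >= 1 by theory
        df = len(cols)
        rows[name] = {
            "gvif": g,
            "df": df,
            "gvif_scaled": g ** (1.0 / (2 * df)) if np.isfinite(g) else np.inf,
            "flagged": not g < threshold,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if out["flagged"].any():
        log.warning("gvif: collinearity flagged for %s",
                    ", ".join(out.index[out["flagged"]]))
    return GVIFReport(out, threshold)


@dataclass
class RFFit:
    """A fitted attribution forest with its out-of-bag summary."""

    model: RandomForestRegressor
    X: pd.DataFrame  # dummy-coded design actually used (complete rows)
    y: np.ndarray
    groups: dict
    response: str
    n_trees: int
    mtry: int
    seed: int
    oob_mse: float
    var_explained: float  # %, 100 * (1 - OOB-MSE / var(y))
    n_dropped: int  # rows removed by listwise deletion


def fit_rf(
    table: pd.DataFrame,
    response: str = "effort",
    n_trees: int = 1000,
    mtry: int | None = None,
    seed: int = 0,
    min_rows: int = 30,
) -> RFFit:
    """Fit a seeded regression forest of ``n_trees`` bootstrap trees.

    ``mtry`` (predictors sampled per split) defaults to a third of the
    seven predictors, i.e. 2.  Rows with any missing predictor or response
    are dropped listwise (count logged).  Leaf size is the conventional
    regression default of 5.
    """
    ycol = RESPONSES.get(response, response)
    if ycol not in table.columns:
        raise SchemaError(f"response column {ycol!r} not in covariate table")
    X_all, groups = design_matrix(table)
    full = pd.concat([X_all, table[ycol].rename("__y__")], axis=1)
    kept = full.dropna()
    n_dropped = len(full) - len(kept)
    if n_dropped:
        log.info("fit_rf: dropped %d incomplete row(s)", n_dropped)
    if len(kept) < min_rows:
        raise InsufficientDataError(
            f"random forest needs >= {min_rows} complete rows, got {len(kept)}"
        )
    X = kept.drop(columns="__y__")
    y = kept["__y__"].to_numpy(dtype=float)
    if mtry is None:
        mtry = max(1, len(PREDICTORS) // 3)
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=5,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X.to_numpy(), y)
    oob_mse = float(np.mean((y - model.oob_prediction_) ** 2))
    var_explained = 100.0 * (1.0 - oob_mse / np.var(y, ddof=1))
    return RFFit(
        model=model,
        X=X,
        y=y,
        groups=groups,
        response=response,
        n_trees=n_trees,
        mtry=mtry,
        seed=seed,
        oob_mse=oob_mse,
        var_explained=var_explained,
        n_dropped=n_dropped,
    )


def _oob_indices(tree_seed, n: int) -> np.ndarray:
    """Out-of-bag sample indices of one bootstrap tree."""
    try:
        import inspect

        from sklearn.ensemble._forest import (
            _generate_unsampled_indices,
            _get_n_samples_bootstrap,
        )

        if "sample_weight" in inspect.signature(_get_n_samples_bootstrap).parameters:
            nsb = _get_n_samples_bootstrap(n, None, None)
            return _generate_unsampled_indices(tree_seed, n, nsb, None)
        nsb = _get_n_samples_bootstrap(n, None)
        return _generate_unsampled_indices(tree_seed, n, nsb)
    except (ImportError, TypeError):  # pragma: no cover - replicate the draw
        from sklearn.utils import check_random_state

        sampled = check_random_state(tree_seed).randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        return np.where(mask)[0]


def permutation_importance(fit: RFFit) -> pd.Series:
    """%IncMSE per predictor: OOB MSE increase under permutation.

    For each tree, the MSE on its out-of-bag cases is recomputed after
    permuting one predictor (a factor's indicator columns are permuted
    jointly); the mean increase over trees, as a percentage of the baseline
    OOB MSE, is the importance.  Predictors are returned ranked descending.
    """
    Xv = fit.X.to_numpy()
    y = fit.y
    n = len(y)
    colpos = {c: i for i, c in enumerate(fit.X.columns)}
    rng = np.random.default_rng(np.uint32(fit.seed) + np.uint32(0x5EED))
    base = []
    inc: dict[str, list] = {g: [] for g in fit.groups}
    for tree in fit.model.estimators_:
        oob = _oob_indices(tree.random_state, n)
        if len(oob) == 0:
            continue
        Xo = Xv[oob]
        yo = y[oob]
        e0 = float(np.mean((tree.predict(Xo) - yo) ** 2))
        base.append(e0)
        for name, cols in fit.groups.items():
            j = [colpos[c] for c in cols]
            perm = rng.permutation(len(oob))
            Xp = Xo.copy()
            Xp[:, j] = Xo[np.ix_(perm, j)]
            ep = float(np.mean((tree.predict(Xp) - yo) ** 2))
            inc[name].append(ep - e0)
    baseline = float(np.mean(base))
    pct = {g: 100.0 * float(np.mean(v)) / baseline for g, v in inc.items()}
    return pd.Series(pct, name="pct_inc_mse").sort_values(ascending=False)


def partial_dependence(fit: RFFit, predictor: str, n_grid: int = 20) -> pd.DataFrame:
    """Partial dependence curve of one predictor.

    For each grid value v the predictor is forced to v in every row and the
    forest predictions are averaged.  Continuous predictors use an
    ``n_grid``-point grid spanning the observed range; binary and factor
    predictors use their level set.
    """
    if predictor not in fit.groups:
        raise ValueError(f"unknown predictor {predictor!r}")
    Xv = fit.X.to_numpy()
    rows = []
    if predictor == "quarter":
        for level in (1, 2, 3, 4):
            Xm = Xv.copy()
            for other in (2, 3, 4):
                Xm[:, fit.X.columns.get_loc(f"quarter_{other}")] = float(other == level)
            rows.append((float(level), float(fit.model.predict(Xm).mean())))
    else:
        col = fit.X.columns.get_loc(predictor)
        observed = np.unique(Xv[:, col])
        if len(observed) <= max(n_grid, 2) and np.all(np.isin(observed, (0.0, 1.0))):
            grid = observed  # binary flag: level set
        elif len(observed) <= n_grid:
            grid = observed
        else:
            grid = np.linspace(observed.min(), observed.max(), n_grid)
        for v in grid:
            Xm = Xv.copy()
            Xm[:, col] = v
            rows.append((float(v), float(fit.model.predict(Xm).mean())))
    return pd.DataFrame(rows, columns=["value", "prediction"])
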