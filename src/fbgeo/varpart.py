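"""Environmental-driver analysis: collinearity filtering, model selection,
redundancy analysis and variance partitioning.

For a single standardized response, redundancy analysis (RDA) reduces to
ordinary least squares: the explained fraction is R^2, and the currency
of variance partitioning is the Ezekiel-adjusted R^2,

    adjR2 = 1 - (1 - R2) * (n - 1) / (n - p - 1).

The partition assigns each explanatory group (soil, land management,
climate, spatial descriptors) its *unique* fraction — the drop in
adjusted R^2 when the group is removed from the full model (partial RDA)
— and lumps the remainder of the explained variance into a shared
("interactions") fraction so that unique fractions plus shared equal the
full-model adjusted R^2 exactly.  Group significance comes from
Freedman-Lane residual-permutation pseudo-F tests conditioned on the
other groups.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VIF_THRESHOLD_DEFAULT = 5.0
MAX_EXHAUSTIVE_COLUMNS = 20


class VarPartError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Core least squares / RDA
# ---------------------------------------------------------------------------

def _ols_r2(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    """R^2 and coefficients of y on [1, X]; empty X gives the null model."""
    n = len(y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise VarPartError("response has zero variance")
    if X.shape[1] == 0:
        return 0.0, np.array([])
    A = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        logger.warning("rank-deficient design (rank %d < %d columns)", rank, A.shape[1])
    resid = y - A @ coef
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return r2, coef[1:]


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment; may be negative for weak models."""
    if n - p - 1 <= 0:
        raise VarPartError(f"too few observations (n={n}) for {p} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class RdaFit:
    r_squared: float
    adj_r_squared: float
    coefficients: pd.Series  # standardized estimates per column
    pseudo_f: float
    df_model: int
    df_resid: int
    n: int


def rda_fit(y: np.ndarray, X: pd.DataFrame) -> RdaFit:
    """Univariate RDA = OLS of the (standardized) response on the predictors."""
    y = np.asarray(y, dtype=float)
    n, p = len(y), X.shape[1]
    if n <= p + 1:
        raise VarPartError(f"need n > p + 1 (n={n}, p={p})")
    r2, coef = _ols_r2(y, X.to_numpy(float))
    df_resid = n - p - 1
    pseudo_f = (r2 / p) / ((1.0 - r2) / df_resid) if p > 0 and r2 < 1 else np.inf
    return RdaFit(
        r_squared=r2,
        adj_r_squared=adjusted_r2(r2, n, p),
        coefficients=pd.Series(coef, index=list(X.columns)),
        pseudo_f=float(pseudo_f),
        df_model=p,
        df_resid=df_resid,
        n=n,
    )


# ---------------------------------------------------------------------------
# Predictor preparation and collinearity filtering
# ---------------------------------------------------------------------------

def prepare_predictors(
    df: pd.DataFrame,
    quantitative: list[str],
    categorical: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Standardize quantitative columns and dummy-encode categoricals.

    Returns the model matrix and the list of dummy column names (exempt
    from VIF filtering).  Categorical columns are treatment-coded: the
    first level (alphabetical) is the reference and is dropped.
    """
    parts = []
    for col in quantitative:
        v = df[col].to_numpy(float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise VarPartError(f"column {col!r} is constant")
        parts.append(pd.Series((v - v.mean()) / sd, name=col, index=df.index))
    dummy_cols: list[str] = []
    for col in categorical or []:
        dummies = pd.get_dummies(df[col], prefix=col, drop_first=True, dtype=float)
        dummy_cols.extend(dummies.columns)
        parts.append(dummies)
    X = pd.concat(parts, axis=1)
    if X.isna().any().any():
        raise VarPartError("missing values in prepared predictors")
    return X, dummy_cols


def vif_filter(
    X: pd.DataFrame,
    threshold: float = VIF_THRESHOLD_DEFAULT,
    exempt: list[str] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Iteratively drop the worst-collinear column until all VIF <= threshold.

    VIF_j = 1 / (1 - R2_j) where R2_j regresses column j on all other
    retained columns.  Columns in ``exempt`` (typically category
    dummies) are never removed but still serve as regressors.  Exact
    duplicates are removed first.  Returns the retained frame and a
    per-iteration trace.
    """
    exempt = set(exempt or [])
    X = X.copy()
    # exact duplicates make the design singular before VIF is computable
    seen: dict[bytes, str] = {}
    for col in list(X.columns):
        key = np.ascontiguousarray(X[col].to_numpy(float)).tobytes()
        if key in seen and col not in exempt:
            logger.info("dropping exact duplicate column %r (= %r)", col, seen[key])
            X = X.drop(columns=[col])
        else:
            seen.setdefault(key, col)
    trace: list[dict] = []
    while True:
        candidates = [c for c in X.columns if c not in exempt]
        if len(candidates) == 0 or X.shape[1] < 2:
            break
        vifs = {}
        Xv = X.to_numpy(float)
        for j, col in enumerate(X.columns):
            if col not in candidates:
                continue
            others = np.delete(Xv, j, axis=1)
            r2, _ = _ols_r2(Xv[:, j], others)
            vifs[col] = 1.0 / (1.0 - r2) if r2 < 1.0 else np.inf
        worst = max(vifs, key=vifs.get)  # type: ignore[arg-type]
        trace.append({"vifs": dict(vifs), "removed": None})
        if vifs[worst] <= threshold:
            break
        trace[-1]["removed"] = worst
        X = X.drop(columns=[worst])
    return X, trace


def best_subset_bic(
    y: np.ndarray, X: pd.DataFrame, max_size: int | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Exhaustive best-subset screen by BIC.

    Enumerates all subsets up to ``max_size`` (default: all columns) and
    returns the BIC-minimising subset plus a per-size table of best BIC
    and adjusted R^2.  The null (empty) model competes: pure-noise
    responses select the empty subset.
    """
    y = np.asarray(y, dtype=float)
    n, ncol = len(y), X.shape[1]
    if ncol > MAX_EXHAUSTIVE_COLUMNS:
        raise VarPartError(
            f"{ncol} columns is too many for exhaustive search "
            f"(max {MAX_EXHAUSTIVE_COLUMNS}); pre-filter with vif_filter/forward_select"
        )
    max_size = ncol if max_size is None else min(max_size, ncol)
    Xv = X.to_numpy(float)

    def bic_of(cols: tuple[int, ...]) -> tuple[float, float]:
        r2, _ = _ols_r2(y, Xv[:, list(cols)])
        rss = (1.0 - r2) * float(np.sum((y - y.mean()) ** 2))
        k = len(cols) + 1  # slopes + intercept
        bic = n * np.log(max(rss, 1e-300) / n) + k * np.log(n)
        return float(bic), r2

    best_cols: tuple[int, ...] = ()
    best_bic, _ = bic_of(())
    null_bic = best_bic
    rows = [{"size": 0, "bic": best_bic, "adj_r_squared": 0.0, "columns": []}]
    for size in range(1, max_size + 1):
        size_best = None
        for cols in itertools.combinations(range(ncol), size):
            bic, r2 = bic_of(cols)
            if size_best is None or bic < size_best[0]:
                size_best = (bic, r2, cols)
        assert size_best is not None
        bic, r2, cols = size_best
        rows.append(
            {
                "size": size,
                "bic": bic,
                "adj_r_squared": adjusted_r2(r2, n, size),
                "columns": [X.columns[j] for j in cols],
            }
        )
        if bic < best_bic:
            best_bic, best_cols = bic, cols
    if not best_cols:
        logger.info("best-subset: no subset beats the null model (BIC %.2f)", null_bic)
    return [X.columns[j] for j in best_cols], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------

def permutation_test(
    y: np.ndarray,
    X: pd.DataFrame,
    Z: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pseudo-F permutation test of X (optionally conditioned on Z).

    F = (R2_added / p_added) / ((1 - R2_full) / df_resid).  Without
    conditioning, rows of y are permuted; with conditioning, residuals
    of the reduced model y ~ Z are permuted and re-added to its fitted
    values (Freedman-Lane).  p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise VarPartError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(float)
    p_added = Xv.shape[1]
    if Z is not None and Z.shape[1] > 0:
        Zv = Z.to_numpy(float)
        A = np.column_stack([np.ones(n), Zv])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        fitted = A @ coef
        resid = y - fitted
        full = np.column_stack([Zv, Xv])
    else:
        Zv = np.empty((n, 0))
        fitted = np.full(n, y.mean())
        resid = y - fitted
        full = Xv

    def stat(yy: np.ndarray) -> float:
        r2_red, _ = _ols_r2(yy, Zv)
        r2_full, _ = _ols_r2(yy, full)
        df_resid = n - full.shape[1] - 1
        denom = (1.0 - r2_full) / df_resid
        if denom <= 0:
            return np.inf
        return ((r2_full - r2_red) / p_added) / denom

    f_obs = stat(y)
    count = 0
    for _ in range(n_perm):
        y_star = fitted + rng.permutation(resid)
        if stat(y_star) >= f_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return float(f_obs), float(p)


@dataclass
class ForwardSelection:
    selected: list[str]
    p_values: list[float]
    adj_r2_path: list[float]
    fit: RdaFit | None
    full_adj_r2: float


def forward_select(
    y: np.ndarray,
    X: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> ForwardSelection:
    """Greedy forward selection maximising adjusted R^2 with a double stop.

    At each step the candidate giving the largest adjusted-R^2 gain is
    tested by a conditioned permutation test; it enters only if its p is
    below ``alpha`` *and* the running adjusted R^2 stays at or below the
    full-model adjusted R^2 (the global ceiling), mirroring the
    stopping rules of stepwise constrained ordination.
    """
    y = np.asarray(y, dtype=float)
    full_adj = rda_fit(y, X).adj_r_squared if X.shape[1] > 0 else 0.0
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    pvals: list[float] = []
    path: list[float] = []
    current_adj = 0.0
    remaining = list(X.columns)
    n = len(y)
    while remaining:
        gains = []
        for col in remaining:
            cols = selected + [col]
            r2, _ = _ols_r2(y, X[cols].to_numpy(float))
            gains.append(adjusted_r2(r2, n, len(cols)))
        j = int(np.argmax(gains))
        cand, cand_adj = remaining[j], gains[j]
        if cand_adj <= current_adj or cand_adj > full_adj + 1e-12:
            break
        Z = X[selected] if selected else None
        _, p = permutation_test(
            y, X[[cand]], Z=Z, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        if p >= alpha:
            break
        selected.append(cand)
        pvals.append(p)
        path.append(cand_adj)
        current_adj = cand_adj
        remaining.remove(cand)
    fit = rda_fit(y, X[selected]) if selected else None
    return ForwardSelection(
        selected=selected,
        p_values=pvals,
        adj_r2_path=path,
        fit=fit,
        full_adj_r2=full_adj,
    )


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VarPartResult:
    unique: dict[str, float]  # adjusted-R^2 units; small negatives possible
    shared: float
    total: float
    p_values: dict[str, float] = field(default_factory=dict)
    fit: RdaFit | None = None

    def to_dict(self) -> dict:
        return {
            "unique": dict(self.unique),
            "shared": self.shared,
            "total": self.total,
            "p_values": dict(self.p_values),
        }


def variance_partition(
    y: np.ndarray,
    groups: dict[str, pd.DataFrame],
    n_perm: int = 999,
    seed: int | None = None,
) -> VarPartResult:
    """Partition explained variance among explanatory groups by partial RDA.

    unique(g) = adjR2(all groups) - adjR2(all but g); the shared
    ("interactions") fraction is total - sum(unique), so the identity
    sum(unique) + shared = total holds exactly.  Per-group p-values come
    from Freedman-Lane tests of g conditioned on the remaining groups.
    Negative unique fractions are reported as-is.
    """
    if len(groups) < 2:
        raise VarPartError("need at least two explanatory groups")
    for name, g in groups.items():
        if g.shape[1] == 0:
            raise VarPartError(f"group {name!r} has no columns")
    y = np.asarray(y, dtype=float)
    all_X = pd.concat(groups.values(), axis=1)
    fit_all = rda_fit(y, all_X)
    total = fit_all.adj_r_squared
    rng = np.random.default_rng(seed)
    unique: dict[str, float] = {}
    pvals: dict[str, float] = {}
    for name in groups:
        others = pd.concat([g for gname, g in groups.items() if gname != name], axis=1)
        reduced = rda_fit(y, others)
        unique[name] = total - reduced.adj_r_squared
        _, p = permutation_test(
            y, groups[name], Z=others, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        pvals[name] = p
    shared = total - sum(unique.values())
    return VarPartResult(unique=unique, shared=shared, total=total, p_values=pvals, fit=fit_all)
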