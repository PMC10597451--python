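"""Response conditioning: normality screen, Box-Cox transform, Grubbs outliers.

The downstream models assume roughly Gaussian, homoskedastic responses.
The conditioning chain is: Shapiro-Wilk normality check; if rejected, a
Box-Cox power transform with lambda chosen by profile likelihood; then
iterative Grubbs outlier removal on the transformed scale.  The chosen
transform is recorded in a :class:`TransformSpec` so any downstream
result can be traced back to raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

BOXCOX_LAMBDA_BOUNDS = (-2.0, 2.0)
GRUBBS_ALPHA_DEFAULT = 0.05
GRUBBS_MAX_ITER_DEFAULT = 5


@dataclass(frozen=True)
class TransformSpec:
    """A recorded, invertible response transform.

    kind 'identity' leaves data untouched, 'log' is the natural log and
    'boxcox' is (x^lam - 1)/lam (natural log at lam = 0).  ``shift`` is
    added before transforming, for responses touching zero.
    """

    kind: str  # identity | log | boxcox
    lam: float | None = None
    shift: float = 0.0

    def __post_init__(self):
        if self.kind not in ("identity", "log", "boxcox"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "boxcox" and self.lam is None:
            raise ValueError("boxcox transform requires lambda")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "lambda": self.lam, "shift": self.shift}


def shapiro_normality(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value (Royston approximation, 3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant data: normality test undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def boxcox_lambda(
    x: np.ndarray, bounds: tuple[float, float] = BOXCOX_LAMBDA_BOUNDS
) -> float:
    """Box-Cox lambda maximising the Gaussian profile log-likelihood."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive data (use a shift)")
    lam = stats.boxcox_normmax(x, brack=bounds, method="mle")
    return float(np.clip(lam, *bounds))


def boxcox_apply(x: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Apply a TransformSpec; strictly increasing for every lambda."""
    x = np.asarray(x, dtype=float) + spec.shift
    if spec.kind == "identity":
        return x
    if np.any(x <= 0):
        raise ValueError("non-positive values after shift: transform undefined")
    if spec.kind == "log" or (spec.kind == "boxcox" and spec.lam == 0):
        return np.log(x)
    return (x**spec.lam - 1.0) / spec.lam


def boxcox_invert(y: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Inverse of :func:`boxcox_apply`."""
    y = np.asarray(y, dtype=float)
    if spec.kind == "identity":
        return y - spec.shift
    if spec.kind == "log" or (spec.kind == "boxcox" and spec.lam == 0):
        return np.exp(y) - spec.shift
    return (spec.lam * y + 1.0) ** (1.0 / spec.lam) - spec.shift


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))


@dataclass
class OutlierReport:
    removed_indices: list[int] = field(default_factory=list)
    g_statistics: list[float] = field(default_factory=list)
    critical_values: list[float] = field(default_factory=list)
    alpha: float = GRUBBS_ALPHA_DEFAULT

    def to_dict(self) -> dict:
        return {
            "removed_indices": list(self.removed_indices),
            "g_statistics": list(self.g_statistics),
            "critical_values": list(self.critical_values),
            "alpha": self.alpha,
        }


def grubbs_filter(
    x: np.ndarray,
    alpha: float = GRUBBS_ALPHA_DEFAULT,
    max_iter: int = GRUBBS_MAX_ITER_DEFAULT,
) -> tuple[np.ndarray, OutlierReport]:
    """Iterative two-sided Grubbs outlier removal.

    Each pass computes G = max|x_i - mean| / sd and removes the single
    most extreme point if G exceeds the critical value at ``alpha``
    (first index wins on ties); repeats until no outlier or ``max_iter``
    passes.  Returns the cleaned vector and a report with the removed
    original indices in removal order.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("Grubbs test needs n >= 3")
    report = OutlierReport(alpha=alpha)
    keep = np.arange(len(x))
    current = x.copy()
    for _ in range(max_iter):
        if len(current) < 3:
            break
        mean = current.mean()
        sd = current.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(current - mean)
        j = int(np.argmax(dev))  # argmax takes the first maximal index
        g = float(dev[j] / sd)
        crit = grubbs_critical_value(len(current), alpha)
        if g <= crit:
            break
        report.removed_indices.append(int(keep[j]))
        report.g_statistics.append(g)
        report.critical_values.append(crit)
        current = np.delete(current, j)
        keep = np.delete(keep, j)
    return current, report


@dataclass
class PrepResult:
    """Outcome of the full conditioning chain on one response."""

    values: np.ndarray  # transformed, outliers removed
    kept_indices: np.ndarray  # positions in the input vector
    spec: TransformSpec
    shapiro_w: float
    shapiro_p: float
    outliers: OutlierReport


def prepare_response(
    x: np.ndarray,
    alpha_normality: float = 0.05,
    grubbs_alpha: float = GRUBBS_ALPHA_DEFAULT,
    grubbs_max_iter: int = GRUBBS_MAX_ITER_DEFAULT,
) -> PrepResult:
    """Normality check -> Box-Cox if rejected -> Grubbs on the transformed scale.

    Non-positive responses are shifted to be strictly positive before a
    Box-Cox transform (shift = 1e-6 - min(x) when needed).
    """
    x = np.asarray(x, dtype=float)
    w, p = shapiro_normality(x)
    if p < alpha_normality:
        shift = 0.0 if x.min() > 0 else float(1e-6 - x.min())
        lam = boxcox_lambda(x + shift)
        spec = TransformSpec(kind="boxcox", lam=lam, shift=shift)
    else:
        spec = TransformSpec(kind="identity")
    y = boxcox_apply(x, spec)
    cleaned, report = grubbs_filter(y, alpha=grubbs_alpha, max_iter=grubbs_max_iter)
    kept = np.setdiff1d(np.arange(len(x)), np.array(report.removed_indices, dtype=int))
    return PrepResult(
        values=cleaned,
        kept_indices=kept,
        spec=spec,
        shapiro_w=w,
        shapiro_p=p,
        outliers=report,
    )
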