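"""Land-use contrasts: tie-corrected Kruskal-Wallis and Bonferroni post hoc.

The omnibus test is the rank-based Kruskal-Wallis H with tie correction,
referred to a chi-square with k-1 df.  Pairwise follow-up uses the
rank-LSD convention (difference of mean ranks against a Student-t
quantile with the pooled rank variance, as in agricolae-style
``kruskal``), with raw p-values Bonferroni-multiplied by the number of
pairs and capped at 1.  Groups that cannot be distinguished share a
letter in the compact letter display.  Because ranks are invariant under
strictly monotone transforms, H is unchanged by any upstream Box-Cox.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class GroupError(ValueError):
    pass


@dataclass
class KwResult:
    h_statistic: float
    df: int
    p_value: float
    mean_ranks: pd.Series
    group_sizes: pd.Series
    pairwise: pd.DataFrame | None = None  # Bonferroni-adjusted p per pair
    letters: pd.Series | None = None

    def to_dict(self) -> dict:
        out = {
            "H": self.h_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "mean_ranks": self.mean_ranks.to_dict(),
            "group_sizes": {k: int(v) for k, v in self.group_sizes.items()},
        }
        if self.pairwise is not None:
            out["pairwise_p"] = {
                f"{a}|{b}": float(self.pairwise.loc[a, b])
                for a in self.pairwise.index
                for b in self.pairwise.columns
                if a < b
            }
        if self.letters is not None:
            out["letters"] = self.letters.to_dict()
        return out


def _validate(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise GroupError("values and labels differ in length")
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise GroupError("need at least two groups")
    if (counts < 2).any():
        bad = uniq[counts < 2]
        raise GroupError(f"groups with fewer than two observations: {list(bad)}")
    return values, labels


def kruskal_wallis(values: np.ndarray, labels: np.ndarray) -> KwResult:
    """Tie-corrected Kruskal-Wallis omnibus test."""
    values, labels = _validate(values, labels)
    n = len(values)
    ranks = stats.rankdata(values)
    uniq = np.unique(labels)
    mean_ranks = pd.Series(
        {g: float(ranks[labels == g].mean()) for g in uniq}, name="mean_rank"
    )
    sizes = pd.Series({g: int((labels == g).sum()) for g in uniq}, name="n")
    grand = (n + 1) / 2.0
    h = (12.0 / (n * (n + 1))) * float(
        sum(sizes[g] * (mean_ranks[g] - grand) ** 2 for g in uniq)
    )
    # tie correction: divide by 1 - sum(t^3 - t) / (N^3 - N)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    correction = 1.0 - tie_term / (n**3 - n)
    if correction <= 0:
        raise GroupError("all values tied: H undefined")
    h /= correction
    df = len(uniq) - 1
    p = float(stats.chi2.sf(h, df))
    return KwResult(
        h_statistic=float(h),
        df=df,
        p_value=p,
        mean_ranks=mean_ranks,
        group_sizes=sizes,
    )


def _compact_letters(order: list, nonsig: pd.DataFrame) -> pd.Series:
    """Compact letter display from a mutual non-significance matrix.

    ``order`` lists groups best-first; maximal runs of mutually
    non-distinguishable groups share a letter.
    """
    k = len(order)
    runs: list[set] = []
    for i in range(k):
        j = i
        while j + 1 < k and all(
            nonsig.loc[order[a], order[b]]
            for a in range(i, j + 2)
            for b in range(a + 1, j + 2)
        ):
            j += 1
        run = set(order[i : j + 1])
        if not any(run <= r for r in runs):
            runs.append(run)
    letters = {g: "" for g in order}
    for letter_idx, run in enumerate(runs):
        ch = chr(ord("a") + letter_idx)
        for g in run:
            letters[g] += ch
    return pd.Series(letters, name="letters")


def pairwise_posthoc(
    values: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    method: str = "lsd",
) -> KwResult:
    """Omnibus Kruskal-Wallis plus Bonferroni-adjusted pairwise comparisons.

    method 'lsd' (default): mean-rank differences against a t quantile
    with the pooled rank variance, scaled by (N-1-H)/(N-k).  method
    'dunn': normal z-tests with the tie-corrected rank variance.  Raw p
    are multiplied by k(k-1)/2 and capped at 1.
    """
    values, labels = _validate(values, labels)
    res = kruskal_wallis(values, labels)
    uniq = list(res.mean_ranks.index)
    k = len(uniq)
    n = len(values)
    ranks = stats.rankdata(values)
    n_pairs = k * (k - 1) // 2
    pmat = pd.DataFrame(np.ones((k, k)), index=uniq, columns=uniq)
    if method == "lsd":
        s2 = float(np.var(ranks, ddof=1))
        factor = s2 * (n - 1 - res.h_statistic) / (n - k)
        dof = n - k
        for a in range(k):
            for b in range(a + 1, k):
                ga, gb = uniq[a], uniq[b]
                se = np.sqrt(factor * (1.0 / res.group_sizes[ga] + 1.0 / res.group_sizes[gb]))
                tstat = abs(res.mean_ranks[ga] - res.mean_ranks[gb]) / se
                raw = 2.0 * float(stats.t.sf(tstat, dof))
                pmat.loc[ga, gb] = pmat.loc[gb, ga] = min(1.0, raw * n_pairs)
    elif method == "dunn":
        _, tie_counts = np.unique(values, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var0 = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
        for a in range(k):
            for b in range(a + 1, k):
                ga, gb = uniq[a], uniq[b]
                se = np.sqrt(var0 * (1.0 / res.group_sizes[ga] + 1.0 / res.group_sizes[gb]))
                z = abs(res.mean_ranks[ga] - res.mean_ranks[gb]) / se
                raw = 2.0 * float(stats.norm.sf(z))
                pmat.loc[ga, gb] = pmat.loc[gb, ga] = min(1.0, raw * n_pairs)
    else:
        raise GroupError(f"unknown post-hoc method {method!r}")
    np.fill_diagonal(pmat.values, 1.0)
    order = list(res.mean_ranks.sort_values(ascending=False).index)
    nonsig = pmat >= alpha
    res.pairwise = pmat
    res.letters = _compact_letters(order, nonsig)
    return res


def threshold_fractions(
    values: np.ndarray,
    labels: np.ndarray,
    low: float = 1.0,
    high: float = 5.0,
) -> pd.DataFrame:
    """Per-group percentage of values below ``low`` and above ``high``.

    Used for the tail summaries of F:B ratios (share of soils with
    ratios below 1 or above 5 within each land use).
    """
    if not low < high:
        raise GroupError("thresholds must satisfy low < high")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    rows = []
    for g in np.unique(labels):
        v = values[labels == g]
        rows.append(
            {
                "group": g,
                "n": len(v),
                "pct_below_low": 100.0 * float(np.mean(v < low)),
                "pct_above_high": 100.0 * float(np.mean(v > high)),
            }
        )
    return pd.DataFrame(rows).set_index("group")
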