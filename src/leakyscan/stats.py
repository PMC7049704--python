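"""Group-level statistics: normalization, fold changes and one-sided KS tests.

Used to ask whether translation efficiency falls with uAUG count / distance
from the TSS, and whether upf1-dependent (NMD) stabilisation rises with uAUG
count, position and Kozak score. Counts are normalized by median-of-ratios
size factors, fold changes are pseudocounted log2 ratios of group means, and
group contrasts use the one-sided two-sample Kolmogorov-Smirnov test with the
asymptotic tail p = exp(-2 m n D^2 / (m + n)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


def median_ratio_normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors (genes x samples), scaled to geometric mean 1.

    The per-sample factor is the median over genes (nonzero in every sample)
    of count / geometric-mean-across-samples; normalized counts are
    count / factor. Adding an all-zero gene cannot change the factors.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = mat[nonzero]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geomean, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    factors = pd.Series(factors, index=counts.columns, name="size_factor")
    return factors, counts / factors


def log2fc(wt_mean, mut_mean, pseudocount: float = 1.0):
    """Per-gene log2((mut + pc) / (wt + pc)) on normalized means."""
    return np.log2((np.asarray(mut_mean, float) + pseudocount)
                   / (np.asarray(wt_mean, float) + pseudocount))


def ks_one_sided(
    x, y, alternative: str = "y_greater", method: str = "auto"
) -> tuple[float, float]:
    """One-sided two-sample Kolmogorov-Smirnov test.

    alternative='y_greater' tests whether ``y`` is stochastically greater
    than ``x`` (its CDF lies below), with statistic D+ = sup(F_x - F_y);
    'y_less' uses D- = sup(F_y - F_x). The asymptotic one-sided p is
    exp(-2 m n D^2 / (m + n)); with both samples of size <= 25 (or
    method='exact') the exact distribution is used instead.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if alternative not in ("y_greater", "y_less"):
        raise ValueError("alternative must be 'y_greater' or 'y_less'")
    if alternative == "y_less":
        d, _ = ks_one_sided(y, x, "y_greater", method="asymptotic")
    else:
        grid = np.concatenate([x, y])
        fx = np.searchsorted(x, grid, side="right") / x.size
        fy = np.searchsorted(y, grid, side="right") / y.size
        d = float(np.max(fx - fy))
    d = max(d, 0.0)
    m, n = x.size, y.size
    use_exact = method == "exact" or (method == "auto" and max(m, n) <= 25)
    if use_exact:
        scipy_alt = "greater" if alternative == "y_greater" else "less"
        res = sps.ks_2samp(x, y, alternative=scipy_alt, method="exact")
        return d, float(res.pvalue)
    p = float(np.exp(-2.0 * m * n * d * d / (m + n)))
    return d, min(1.0, p)


@dataclass
class GroupComparison:
    """Values split into ordered groups plus adjacent-pair one-sided KS tests."""

    mode: str
    groups: dict[str, np.ndarray]
    tests: pd.DataFrame  # columns: group_a, group_b, D, p, n_a, n_b

    @property
    def medians(self) -> pd.Series:
        return pd.Series({k: float(np.median(v)) for k, v in self.groups.items()})

    @property
    def sizes(self) -> pd.Series:
        return pd.Series({k: len(v) for k, v in self.groups.items()})


def _adjacent_tests(groups: dict[str, np.ndarray], alternative: str) -> pd.DataFrame:
    rows = []
    names = list(groups)
    for a, b in zip(names, names[1:]):
        xa, xb = groups[a], groups[b]
        if len(xa) < 2 or len(xb) < 2:
            logger.info("skipping KS test %s vs %s: group too small", a, b)
            continue
        d, p = ks_one_sided(xa, xb, alternative)
        rows.append((a, b, d, p, len(xa), len(xb)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "D", "p", "n_a", "n_b"])


def group_by_uaug(
    values: pd.Series,
    site_summary: pd.DataFrame,
    mode: str = "count",
    alternative: str = "y_greater",
    score_threshold: float = 0.8,
    score_bins=None,
) -> GroupComparison:
    """Split per-gene values (TE or log2FC) by uAUG metadata and test adjacent groups.

    ``site_summary`` has per-gene columns n_uaug, proximity_class and
    u1_score (NaN without uAUGs). Modes:

    - 'count': groups 0 / 1 / 2+, the classic uORF dose-response contrast;
    - 'proximity': none / 1+ close / 1+ far (TSS-proximal uAUGs are leaked
      past and behave like absent ones);
    - 'score_bin': single-uAUG genes only, split at ``score_threshold``
      (or into the supplied bin edges).

    ``alternative`` is the direction tested for each adjacent pair
    (group_b vs group_a); groups with fewer than 2 members are excluded.
    """
    meta = site_summary.set_index("gene_id")
    vals = values.dropna()
    common = vals.index.intersection(meta.index)
    vals = vals.loc[common]
    meta = meta.loc[common]

    groups: dict[str, np.ndarray] = {}
    if mode == "count":
        n = meta["n_uaug"]
        for name, mask in [("0", n == 0), ("1", n == 1), ("2+", n >= 2)]:
            groups[name] = vals[mask].to_numpy()
    elif mode == "proximity":
        for name in ("none", "1+ close", "1+ far"):
            groups[name] = vals[meta["proximity_class"] == name].to_numpy()
    elif mode == "score_bin":
        single = meta["n_uaug"] == 1
        score = meta.loc[single, "u1_score"]
        v = vals[single]
        if score_bins is None:
            groups[f"score<{score_threshold}"] = v[score < score_threshold].to_numpy()
            groups[f"score>={score_threshold}"] = v[score >= score_threshold].to_numpy()
        else:
            labels = pd.cut(score, bins=score_bins, include_lowest=True)
            for interval in labels.cat.categories:
                groups[str(interval)] = v[labels == interval].to_numpy()
    else:
        raise ValueError("mode must be 'count', 'proximity' or 'score_bin'")

    groups = {k: g for k, g in groups.items() if len(g) >= 2}
    return GroupComparison(mode, groups, _adjacent_tests(groups, alternative))


def quantile_score_bins(scores: pd.Series, n_bins: int = 4) -> np.ndarray:
    """Equal-count bin edges for score_bin mode."""
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(scores.quantile(qs).to_numpy())
    edges[0] -= 1e-9
    return edges
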