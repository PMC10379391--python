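"""Mann-Whitney U comparison of per-species sharing-rate distributions.

The exact mode computes the null distribution of the rank-sum by dynamic
programming over the observed midrank multiset (so ties are handled exactly);
the large-sample mode uses the normal approximation with the standard tie
correction and a continuity correction. Two-sided p-values throughout;
significance is declared at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["MannWhitneyResult", "mann_whitney_u", "compare_sharing"]

EXACT_LIMIT = 20  # auto mode enumerates when n_a + n_b <= this
ALPHA = 0.05


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float          # U statistic of the first sample
    p: float          # two-sided p-value
    method: str       # "exact" | "normal"
    n_a: int
    n_b: int

    @property
    def u_other(self) -> float:
        return self.n_a * self.n_b - self.u


def _exact_two_sided_p(ranks2: np.ndarray, n_a: int, s2_obs: int) -> float:
    """Exact two-sided p for the rank-sum over all C(N, n_a) assignments.

    ranks2 are midranks doubled to integers; s2_obs is the observed doubled
    rank-sum of group a. DP over items counting, for each subset size, the
    number of subsets attaining each doubled sum.
    """
    total = int(ranks2.sum())
    # dp[k, s] = number of k-subsets with doubled rank-sum s
    dp = np.zeros((n_a + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(n_a, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    dist = dp[n_a]
    n_total = dist.sum()
    cdf = dist[: s2_obs + 1].sum() / n_total
    sf_inclusive = dist[s2_obs:].sum() / n_total
    return float(min(1.0, 2.0 * min(cdf, sf_inclusive)))


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    mode: 'exact' (enumeration over the midrank multiset), 'normal'
    (tie-corrected normal approximation with continuity correction), or
    'auto' (exact when n_a + n_b <= 20).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "normal", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if n_a + n_b <= EXACT_LIMIT else "normal"

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0

    if mode == "exact":
        ranks2 = np.rint(ranks * 2).astype(int)
        s2_obs = int(round(2 * r_a))
        p = _exact_two_sided_p(ranks2, n_a, s2_obs)
        return MannWhitneyResult(u=float(u_a), p=p, method="exact",
                                 n_a=n_a, n_b=n_b)

    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return MannWhitneyResult(u=float(u_a), p=1.0, method="normal",
                                 n_a=n_a, n_b=n_b)
    diff = u_a - mu
    z = (diff - np.sign(diff) * 0.5) / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return MannWhitneyResult(u=float(u_a), p=p, method="normal",
                             n_a=n_a, n_b=n_b)


def compare_sharing(rates_pv, rates_bv, alpha: float = ALPHA,
                    include_uncovered: bool = True,
                    coverage: Optional[dict] = None) -> dict:
    """Compare PV vs BV per-species sharing rates.

    rates_pv / rates_bv: mappings or pandas Series of species -> rate in [0,1]
    over the same species set. Species with zero alignment coverage are kept
    as rate 0 by default; pass include_uncovered=False with a `coverage`
    mapping (species -> bool) to drop them from both groups.
    """
    import pandas as pd

    pv = pd.Series(rates_pv, dtype=float)
    bv = pd.Series(rates_bv, dtype=float)
    if set(pv.index) != set(bv.index):
        raise ValueError("PV and BV summaries cover different species sets")
    bv = bv.reindex(pv.index)
    if not include_uncovered:
        if coverage is None:
            raise ValueError("coverage map required when dropping uncovered species")
        keep = [sp for sp in pv.index if coverage.get(sp, True)]
        pv, bv = pv.loc[keep], bv.loc[keep]
    if len(pv) < 2:
        raise ValueError("need at least two species per group for the test")

    res = mann_whitney_u(pv.to_numpy(), bv.to_numpy())
    return {
        "n_species": int(len(pv)),
        "U": res.u,
        "p_value": res.p,
        "method": res.method,
        "median_rate_pv": float(np.median(pv)),
        "median_rate_bv": float(np.median(bv)),
        "alpha": alpha,
        "significant": bool(res.p < alpha),
    }
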