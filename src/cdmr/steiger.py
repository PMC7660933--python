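"""Single-SNP Steiger directionality test and its multi-SNP aggregations.

The test Fisher-transforms the absolute SNP-trait correlations from the two
cohorts, Z_Xg = F(|r_Xg|) and Z_Yg = F(|r_Yg|), and refers

    (Z_Xg - Z_Yg) / sqrt(1/(n_X - 3) + 1/(n_Y - 3))

to a standard normal. A significantly positive statistic is read as X -> Y,
significantly negative as Y -> X. Note the test presupposes that one of the
two causal directions exists: under a no-causal null with associated SNPs it
still forces a directional call at rate ~alpha per direction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SteigerResult",
    "SteigerAggregate",
    "fisher_z",
    "steiger_test",
    "steiger_aggregate",
]

DECISIONS = ("x_to_y", "y_to_x", "inconclusive")


def fisher_z(r: float) -> float:
    """Fisher Z-transform of |r|: 0.5 * ln((1+|r|)/(1-|r|))."""
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    a = abs(r)
    return float(0.5 * np.log((1 + a) / (1 - a)))


@dataclass
class SteigerResult:
    snp_id: str
    z_x: float
    z_y: float
    z_g: float
    var_z: float
    stat: float
    pval: float
    decision: str


@dataclass
class SteigerAggregate:
    """Decision frequencies over SNPs and the majority-vote call."""

    prop: dict[str, float]
    mv_decision: str


def steiger_test(
    r_x: float,
    r_y: float,
    n_x: int,
    n_y: int,
    alpha: float = 0.05,
    snp_id: str = "",
) -> SteigerResult:
    """Two-sided single-SNP Steiger test at level ``alpha``."""
    if n_x <= 3 or n_y <= 3:
        raise ValueError("sample sizes must exceed 3")
    z_x = fisher_z(r_x)
    z_y = fisher_z(r_y)
    z_g = z_x - z_y
    var_z = 1.0 / (n_x - 3) + 1.0 / (n_y - 3)
    stat = z_g / np.sqrt(var_z)
    pval = float(2.0 * stats.norm.sf(abs(stat)))
    if pval > alpha:
        decision = "inconclusive"
    else:
        decision = "x_to_y" if z_g > 0 else "y_to_x"
    return SteigerResult(snp_id, z_x, z_y, z_g, var_z, float(stat), pval, decision)


def steiger_aggregate(results: list[SteigerResult]) -> SteigerAggregate:
    """Pool single-SNP results: decision proportions and majority vote.

    Ties in the vote yield ``inconclusive`` (conservative tie rule).
    """
    if not results:
        raise ValueError("empty result list")
    counts = Counter(r.decision for r in results)
    total = len(results)
    prop = {d: counts.get(d, 0) / total for d in DECISIONS}
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        mv = "inconclusive"
    else:
        mv = top[0][0]
    return SteigerAggregate(prop, mv)
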