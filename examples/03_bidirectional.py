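"""Bi-directional inference with disjoint instrument sets.

Simulates the simultaneous model X = beta2*Y + gamma1*g1 + ..., Y = beta1*X +
gamma2*g2 + ... in three regimes (no effect, X->Y only, both directions) and
applies bi-CD-Ratio: instruments for X estimate K1 (the X->Y arm), instruments
for Y estimate K2. An arm whose CI lies inside [-1,0) or (0,1] supports a
causal effect on that arm; a CI covering 0 supports none.
"""

import numpy as np

from cdmr import LDMatrix, SimScenario, bi_cd_ratio, gwas_scan, simulate_genotypes, simulate_traits
from cdmr.corr import correlation_set, ratio_system
from cdmr.simulate import _genotype_config


def one_replicate(beta1, beta2, seed):
    rng = np.random.default_rng(seed)
    scn = SimScenario(
        m=8, n=30_000, mode="bidirectional", beta1=beta1, beta2=beta2,
        gamma1=0.4, gamma2=0.4, block_cor=0.0,
    )
    cfg = _genotype_config(scn, rng)
    gx = simulate_genotypes(scn, rng, cfg)
    gy = simulate_genotypes(scn, rng, cfg)
    d1 = simulate_traits(gx, scn, rng)
    d2 = simulate_traits(gy, scn, rng)
    sx = gwas_scan(gx, d1.X, trait_label="X")
    sy = gwas_scan(gy, d2.Y, trait_label="Y")
    half = scn.m // 2
    ids1, ids2 = sx.snp_ids[:half], sx.snp_ids[half:]
    ld = LDMatrix(sx.snp_ids, np.corrcoef(gx, rowvar=False))

    def arm(num_stats, den_stats, ids):
        sub_ld = ld.subset(ids)
        return ratio_system(
            correlation_set(den_stats.subset(ids), sub_ld),
            correlation_set(num_stats.subset(ids), sub_ld),
        )

    return bi_cd_ratio(arm(sy, sx, ids1), arm(sx, sy, ids2))


for label, b1, b2 in (
    ("no causal effect", 0.0, 0.0),
    ("uni-directional X->Y", 0.2, 0.0),
    ("bi-directional", 0.2, 0.15),
):
    res = one_replicate(b1, b2, seed=3)
    print(f"{label}: K1 = {res.K1.K_hat:+.3f} CI [{res.K1.ci[0]:+.3f}, {res.K1.ci[1]:+.3f}], "
          f"K2 = {res.K2.K_hat:+.3f} CI [{res.K2.ci[0]:+.3f}, {res.K2.ci[1]:+.3f}] "
          f"-> verdict: {res.verdict.value}")

print("\nEach arm tests its own causal direction with its own valid "
      "instruments, so no/uni/bi-directional relationships are separable.")
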