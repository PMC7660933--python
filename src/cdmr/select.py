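"""Instrument selection: assign SNPs significant for both traits to
predefined LD-independent loci, order by joint significance rank sum, and
greedily prune by pairwise LD.

Within each locus the SNPs' p-values for each trait are ranked ascending
separately, the two ranks summed to I_i = I_Xi + I_Yi, and SNPs visited in
ascending I_i; a SNP is kept iff its absolute correlation with every
already-kept SNP in the locus is below the cutoff (default 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LDMatrix, SummaryStatsTable

__all__ = ["SelectionResult", "select_instruments"]

P_CUT_DEFAULT = 5e-8
COR_CUT_DEFAULT = 0.8


@dataclass
class SelectionResult:
    kept: list[str]
    dropped: list[tuple[str, str]]  # (snp_id, reason)
    locus_of: dict[str, int]
    rank_sum: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"snp_id": s, "status": "kept", "locus": self.locus_of.get(s),
             "rank_sum": self.rank_sum.get(s)}
            for s in self.kept
        ] + [
            {"snp_id": s, "status": reason, "locus": self.locus_of.get(s),
             "rank_sum": self.rank_sum.get(s)}
            for s, reason in self.dropped
        ]
        return pd.DataFrame(rows)


def _assign_locus(chrom: str, pos: int, loci: pd.DataFrame) -> int | None:
    hit = loci[(loci["chrom"] == chrom) & (loci["start"] <= pos) & (pos <= loci["end"])]
    if len(hit) == 0:
        return None
    return int(hit.iloc[0]["locus_id"])


def select_instruments(
    statsX: SummaryStatsTable,
    statsY: SummaryStatsTable,
    ld: LDMatrix,
    loci: pd.DataFrame,
    p_cut: float = P_CUT_DEFAULT,
    cor_cut: float = COR_CUT_DEFAULT,
    within_locus_ranks: bool = True,
) -> SelectionResult:
    """Two-step selection of instruments significant for BOTH traits.

    ``loci`` is a locus table (columns locus_id, chrom, start, end; 1-based
    inclusive, e.g. from :func:`cdmr.io.read_loci_bed`). Rank-sum ties are
    broken by smaller min(p_X, p_Y), then genomic position (deterministic).
    Setting ``within_locus_ranks=False`` ranks p-values genome-wide instead
    of per locus (non-default).
    """
    dfx = statsX.df.set_index("snp_id")
    dfy = statsY.df.set_index("snp_id")
    shared = [s for s in statsX.snp_ids if s in dfy.index]
    dropped: list[tuple[str, str]] = []
    sig = []
    for s in shared:
        if dfx.at[s, "pval"] < p_cut and dfy.at[s, "pval"] < p_cut:
            sig.append(s)
        else:
            dropped.append((s, "not_significant_both"))
    locus_of: dict[str, int] = {}
    by_locus: dict[int, list[str]] = {}
    for s in sig:
        lid = _assign_locus(dfx.at[s, "chrom"], int(dfx.at[s, "pos"]), loci)
        if lid is None:
            dropped.append((s, "no_locus"))
            continue
        locus_of[s] = lid
        by_locus.setdefault(lid, []).append(s)

    rank_sum: dict[str, float] = {}
    if not within_locus_ranks:
        pool = [s for grp in by_locus.values() for s in grp]
        px = pd.Series({s: dfx.at[s, "pval"] for s in pool}).rank(method="average")
        py = pd.Series({s: dfy.at[s, "pval"] for s in pool}).rank(method="average")
        rank_sum.update((px + py).to_dict())

    kept: list[str] = []
    ld_idx = {s: i for i, s in enumerate(ld.snp_ids)}
    for lid in sorted(by_locus):
        grp = by_locus[lid]
        if within_locus_ranks:
            px = pd.Series({s: dfx.at[s, "pval"] for s in grp}).rank(method="average")
            py = pd.Series({s: dfy.at[s, "pval"] for s in grp}).rank(method="average")
            rs = px + py
            rank_sum.update(rs.to_dict())
        else:
            rs = pd.Series({s: rank_sum[s] for s in grp})
        order = sorted(
            grp,
            key=lambda s: (
                rs[s],
                min(dfx.at[s, "pval"], dfy.at[s, "pval"]),
                int(dfx.at[s, "pos"]),
            ),
        )
        kept_here: list[str] = []
        for s in order:
            if s not in ld_idx:
                dropped.append((s, "no_ld"))
                continue
            blocker = next(
                (
                    k
                    for k in kept_here
                    if abs(ld.sigma[ld_idx[s], ld_idx[k]]) >= cor_cut
                ),
                None,
            )
            if blocker is None:
                kept_here.append(s)
            else:
                dropped.append((s, f"pruned_by:{blocker}"))
        kept.extend(kept_here)

    # post-hoc guarantee: the kept set satisfies the pairwise bound
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            if locus_of[a] == locus_of[b]:
                assert abs(ld.sigma[ld_idx[a], ld_idx[b]]) < cor_cut
    return SelectionResult(kept, dropped, locus_of, rank_sum)
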