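"""Reading GWAS summary statistics and reference panels, LD estimation, and
allele harmonization of two summary datasets.

Summary statistics are whitespace/tab-delimited text with a header; the column
names are configurable through a column map because GWAS consortia use many
dialects. Reference panels may be a VCF (GT fields converted to allele-dose
0/1/2) or a plain dosage matrix as TSV (individuals x SNPs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStatsTable",
    "ReferencePanel",
    "LDMatrix",
    "HarmonizedPair",
    "DEFAULT_COLUMN_MAP",
    "read_summary_stats",
    "write_summary_stats",
    "read_vcf_panel",
    "read_dosage_tsv",
    "read_loci_bed",
    "estimate_ld",
    "harmonize",
]

#: Default mapping from canonical field names to file column headers.
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "se": "SE",
    "n": "N",
    "eaf": "EAF",
    "pval": "P",
}

_CANONICAL = list(DEFAULT_COLUMN_MAP)

#: Strand-ambiguous allele pairs (indistinguishable from their complement).
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SummaryStatsTable:
    """Per-SNP marginal GWAS estimates for one trait.

    ``beta`` is the marginal per-allele-dose effect estimate with standard
    error ``se``; ``n`` the GWAS sample size; ``eaf`` the effect-allele
    frequency. Invariants (se > 0, n > 3, 0 < eaf < 1, unique snp_id) are
    enforced at construction: violating rows are dropped and counted in
    ``n_dropped``.
    """

    df: pd.DataFrame
    trait: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        ok = (
            (df["se"] > 0)
            & (df["n"] > 3)
            & (df["eaf"] > 0)
            & (df["eaf"] < 1)
            & (df["pval"] > 0)
            & (df["pval"] <= 1)
            & np.isfinite(df["beta"])
        )
        ok &= ~df["snp_id"].duplicated(keep="first")
        dropped = int((~ok).sum())
        if dropped:
            warnings.warn(
                f"dropped {dropped} summary rows violating invariants", stacklevel=3
            )
        self.df = df.loc[ok].reset_index(drop=True)
        self.n_dropped += dropped
        if len(self.df) == 0:
            raise ValueError("summary-statistics table is empty after filtering")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def subset(self, snp_ids: list[str]) -> "SummaryStatsTable":
        """Rows for ``snp_ids``, in that order."""
        sub = self.df.set_index("snp_id").loc[snp_ids].reset_index()
        return SummaryStatsTable(sub[_CANONICAL], trait=self.trait)


@dataclass
class ReferencePanel:
    """External genotype sample used to estimate SNP-SNP correlations."""

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # individuals x SNPs, values in [0, 2]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape inconsistent with id lists")
        # mean-impute missing dosages per SNP (deterministic, standard)
        if np.isnan(self.dosages).any():
            col_mean = np.nanmean(self.dosages, axis=0)
            idx = np.where(np.isnan(self.dosages))
            self.dosages[idx] = col_mean[idx[1]]
        var = self.dosages.var(axis=0)
        mono = [s for s, v in zip(self.snp_ids, var) if v == 0.0]
        if mono:
            raise ValueError(f"monomorphic SNPs in panel: {mono}")


@dataclass
class LDMatrix:
    """Pairwise Pearson correlation matrix of SNP dosages (unit diagonal)."""

    snp_ids: list[str]
    sigma: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ValueError("sigma shape inconsistent with snp_ids")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        s = 0.5 * (s + s.T)
        np.fill_diagonal(s, 1.0)
        if np.abs(s).max() > 1 + 1e-8:
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.sigma = s

    def subset(self, snp_ids: list[str]) -> "LDMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return LDMatrix(list(snp_ids), self.sigma[np.ix_(idx, idx)])


@dataclass
class HarmonizedPair:
    """Two allele-aligned summary tables plus LD on one shared SNP order."""

    snp_ids: list[str]
    statsX: SummaryStatsTable
    statsY: SummaryStatsTable
    ld: LDMatrix
    flip_log: list = field(default_factory=list)


def read_summary_stats(
    path, column_map: dict | None = None, trait: str = ""
) -> SummaryStatsTable:
    """Read a whitespace/tab-delimited GWAS summary file.

    ``column_map`` maps canonical field names (keys of DEFAULT_COLUMN_MAP) to
    the file's column headers; omitted keys fall back to the defaults.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=r"\s+")
    missing = [cmap[k] for k in _CANONICAL if cmap[k] not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns in {path}: {missing}")
    out = df[[cmap[k] for k in _CANONICAL]].copy()
    out.columns = _CANONICAL
    out["snp_id"] = out["snp_id"].astype(str)
    out["chrom"] = out["chrom"].astype(str)
    for a in ("effect_allele", "other_allele"):
        out[a] = out[a].astype(str).str.upper()
    return SummaryStatsTable(out, trait=trait)


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write in the default dialect at full float precision (round-trips)."""
    df = table.df.copy()
    df.columns = [DEFAULT_COLUMN_MAP[c] for c in df.columns]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_vcf_panel(path) -> ReferencePanel:
    """Load a VCF as a dosage panel (sum of GT alleles; missing -> NaN)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, cols = [], []
    for var in vcf:
        if var.ID is None or len(var.ALT) != 1:
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0,1,3->dose; 2=unknown
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        ids.append(var.ID)
        cols.append(dose)
    return ReferencePanel(samples, ids, np.column_stack(cols))


def read_dosage_tsv(path) -> ReferencePanel:
    """Plain dosage matrix: first column sample id, remaining columns SNPs."""
    df = pd.read_csv(path, sep=r"\s+")
    return ReferencePanel(
        df.iloc[:, 0].astype(str).tolist(),
        list(df.columns[1:]),
        df.iloc[:, 1:].to_numpy(dtype=float),
    )


def read_loci_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> locus table with 1-based inclusive bounds."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
    )
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    df.insert(0, "locus_id", np.arange(1, len(df) + 1))
    return df


def estimate_ld(
    panel: ReferencePanel, snp_ids: list[str] | None = None, shrink: float = 0.0
) -> LDMatrix:
    """Pearson-correlation LD matrix of panel dosages.

    ``shrink`` (lambda in [0,1]) shrinks off-diagonals toward the identity,
    (1-lambda)*Sigma + lambda*I, for near-singular loci; default no shrinkage.
    """
    if snp_ids is None:
        snp_ids = list(panel.snp_ids)
    missing = [s for s in snp_ids if s not in panel.snp_ids]
    if missing:
        raise KeyError(f"SNPs not in panel: {missing}")
    idx = [panel.snp_ids.index(s) for s in snp_ids]
    sub = panel.dosages[:, idx]
    var = sub.var(axis=0)
    if np.any(var == 0):
        bad = [s for s, v in zip(snp_ids, var) if v == 0]
        raise ValueError(f"monomorphic SNPs: {bad}")
    sigma = np.corrcoef(sub, rowvar=False)
    sigma = np.atleast_2d(sigma)
    if shrink:
        m = sigma.shape[0]
        sigma = (1.0 - shrink) * sigma + shrink * np.eye(m)
    return LDMatrix(list(snp_ids), sigma)


def _is_palindromic(a1: str, a2: str) -> bool:
    return (a1, a2) in _PALINDROMIC


def harmonize(
    statsX: SummaryStatsTable,
    statsY: SummaryStatsTable,
    ld: LDMatrix,
    strict_palindromes: bool = True,
) -> HarmonizedPair:
    """Align the two summary tables and the LD matrix on a shared SNP set.

    Where the two datasets code the same SNP with swapped effect/other
    alleles, Y's beta sign is flipped and its eaf replaced by 1-eaf. SNPs with
    irreconcilable alleles are dropped; palindromic (A/T, C/G) SNPs are
    dropped by default because their strand cannot be resolved.
    """
    shared = [s for s in statsX.snp_ids if s in set(statsY.snp_ids) and s in set(ld.snp_ids)]
    if not shared:
        raise ValueError("no shared SNPs between the two datasets and the LD matrix")
    dfx = statsX.df.set_index("snp_id")
    dfy = statsY.df.set_index("snp_id").copy()
    flip_log: list[tuple[str, str]] = []
    kept = []
    for s in shared:
        a1x, a2x = dfx.at[s, "effect_allele"], dfx.at[s, "other_allele"]
        a1y, a2y = dfy.at[s, "effect_allele"], dfy.at[s, "other_allele"]
        if _is_palindromic(a1x, a2x):
            if strict_palindromes:
                flip_log.append((s, "drop_palindromic"))
                continue
            flip_log.append((s, "keep_palindromic"))
        if (a1y, a2y) == (a1x, a2x):
            kept.append(s)
        elif (a1y, a2y) == (a2x, a1x):
            dfy.at[s, "beta"] = -dfy.at[s, "beta"]
            dfy.at[s, "eaf"] = 1.0 - dfy.at[s, "eaf"]
            dfy.at[s, "effect_allele"] = a1x
            dfy.at[s, "other_allele"] = a2x
            flip_log.append((s, "flip_beta"))
            kept.append(s)
        else:
            # try the complementary strand
            c1y, c2y = _COMPLEMENT.get(a1y, "?"), _COMPLEMENT.get(a2y, "?")
            if (c1y, c2y) == (a1x, a2x):
                dfy.at[s, "effect_allele"] = a1x
                dfy.at[s, "other_allele"] = a2x
                flip_log.append((s, "strand_flip"))
                kept.append(s)
            elif (c1y, c2y) == (a2x, a1x):
                dfy.at[s, "beta"] = -dfy.at[s, "beta"]
                dfy.at[s, "eaf"] = 1.0 - dfy.at[s, "eaf"]
                dfy.at[s, "effect_allele"] = a1x
                dfy.at[s, "other_allele"] = a2x
                flip_log.append((s, "strand_and_beta_flip"))
                kept.append(s)
            else:
                flip_log.append((s, "drop_allele_mismatch"))
    if not kept:
        raise ValueError("no SNPs left after allele harmonization")
    sx = SummaryStatsTable(dfx.loc[kept].reset_index()[_CANONICAL], trait=statsX.trait)
    sy = SummaryStatsTable(dfy.loc[kept].reset_index()[_CANONICAL], trait=statsY.trait)
    return HarmonizedPair(kept, sx, sy, ld.subset(kept), flip_log)
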