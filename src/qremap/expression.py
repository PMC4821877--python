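"""Expression-side statistics: CPM, filters, QRE stratification, CDF shifts.

Fragment counts come from summed exonic coverage divided by 100 (the
coverage footprint of one 2x50-bp paired-end fragment) and rounded.
Counts become CPM, quantile-normalized across samples.  Differential
genes satisfy a minimal +/-1.5-fold change (inclusive) plus either an
expression floor (RNA-seq mode: experimental+reference CPM >= 1) or a
q-value cutoff (array mode, q supplied as an input column).

The CDF-shift test asks whether putative direct targets (transcripts
whose longest isoform carries >= 1 QRE) change expression differently
from non-targets: a two-sided Wilcoxon rank-sum test on the per-gene
log2 fold changes of the two strata.  Genes with an NA QRE annotation
are excluded, never counted as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from qremap.junction_array import quantile_normalize

log = logging.getLogger("qremap")

#: pseudocount added to CPM before log2 ratios; the expression floor
#: makes the exact value nearly immaterial, it only prevents infinities
PSEUDOCOUNT = 0.5


def coverage_to_counts(exonic_coverage_sum, fragment_factor: float = 100.0):
    """Summed exonic coverage -> integer fragment count.

    Divides by ``fragment_factor`` (100 bp of coverage per mapped
    paired-end fragment) and rounds half away from zero.
    """
    if fragment_factor <= 0:
        raise ValueError("fragment_factor must be positive")
    cov = np.asarray(exonic_coverage_sum, dtype=float)
    if np.any(cov < 0):
        raise ValueError("coverage must be non-negative")
    counts = np.floor(cov / fragment_factor + 0.5).astype(np.int64)
    return counts if counts.ndim else int(counts)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per column; zero column sums are an error."""
    sums = counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero column sum for sample(s): {', '.join(map(str, zero.index))}")
    return counts / sums * 1e6


def cpm_quantile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """CPM followed by quantile normalization across samples."""
    if counts.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    return quantile_normalize(cpm(counts))


def log2_fold_change(
    cpm_exp: pd.Series, cpm_ref: pd.Series, pseudocount: float = PSEUDOCOUNT
) -> pd.Series:
    """log2((cpm_exp + c) / (cpm_ref + c)) with pseudocount c."""
    return np.log2((cpm_exp + pseudocount) / (cpm_ref + pseudocount))


def filter_expressed(
    df: pd.DataFrame, cpm_sum_cutoff: float = 1.0, exp_col: str = "cpm_exp", ref_col: str = "cpm_ref"
) -> pd.DataFrame:
    """Keep genes with summed CPM over both conditions >= cutoff (inclusive)."""
    keep = (df[exp_col] + df[ref_col]) >= cpm_sum_cutoff
    return df[keep].copy()


def classify_de(
    log2fc: pd.Series,
    fold_cutoff: float = 1.5,
    q_values: pd.Series | None = None,
    q_cutoff: float = 0.05,
) -> pd.Series:
    """Label genes up / down / unchanged.

    ``up`` requires log2fc >= log2(fold_cutoff) (inclusive, "minimally
    +/-1.5-fold"), ``down`` the mirrored bound.  When ``q_values`` are
    supplied (array mode) a call additionally requires q <= q_cutoff.
    """
    if q_values is not None and len(q_values) != len(log2fc):
        raise ValueError("q_values length does not match log2fc")
    thr = np.log2(fold_cutoff)
    status = pd.Series("unchanged", index=log2fc.index, dtype=object)
    status[log2fc >= thr] = "up"
    status[log2fc <= -thr] = "down"
    if q_values is not None:
        status[~(q_values <= q_cutoff)] = "unchanged"
    return status


def venn_qre(df: pd.DataFrame) -> dict[str, int]:
    """Counts of differential genes and their QRE-target intersection.

    Expects ``de_status`` and a boolean ``qre_target`` column; rows with
    NA qre_target are excluded from the intersection counts.
    """
    de = df["de_status"].isin(["up", "down"])
    known = df["qre_target"].notna()
    target = known & df["qre_target"].fillna(False).astype(bool)
    return {
        "n_de": int(de.sum()),
        "n_de_with_qre": int((de & target).sum()),
        "n_up_qre": int((de & target & (df["de_status"] == "up")).sum()),
        "n_down_qre": int((de & target & (df["de_status"] == "down")).sum()),
    }


@dataclass(frozen=True)
class CdfShiftResult:
    """Result of the QRE-stratified fold-change distribution comparison."""

    n_target: int
    n_nontarget: int
    wilcoxon_p: float
    direction: str  # left | right | none
    median_shift: float  # median(target log2fc) - median(non-target log2fc)


def cdf_shift_test(log2fc: Sequence[float], qre_target: Sequence) -> CdfShiftResult:
    """Two-sided Wilcoxon rank-sum of target vs non-target log2 fold changes.

    A right shift (positive median difference) means higher expression
    of QRE targets in the experimental condition.  NA target flags are
    excluded; each stratum must keep >= 2 genes.
    """
    fc = pd.Series(np.asarray(log2fc, dtype=float))
    flags = pd.Series(list(qre_target))
    keep = flags.notna().to_numpy()
    fc, flags = fc[keep], flags[keep].astype(bool)
    t = fc[flags.to_numpy()].to_numpy()
    nt = fc[~flags.to_numpy()].to_numpy()
    if len(t) < 2 or len(nt) < 2:
        raise ValueError(f"need >= 2 genes per stratum, got {len(t)} targets / {len(nt)} non-targets")
    stat, p = stats.ranksums(t, nt)
    shift = float(np.median(t) - np.median(nt))
    direction = "none" if shift == 0 else ("right" if shift > 0 else "left")
    return CdfShiftResult(
        n_target=len(t),
        n_nontarget=len(nt),
        wilcoxon_p=float(p),
        direction=direction,
        median_shift=shift,
    )


def cdf_curves(log2fc: Sequence[float], qre_target: Sequence) -> pd.DataFrame:
    """Empirical CDF curves of log2FC for the target / non-target strata (for plotting)."""
    fc = pd.Series(np.asarray(log2fc, dtype=float))
    flags = pd.Series(list(qre_target))
    keep = flags.notna().to_numpy()
    fc, flags = fc[keep], flags[keep].astype(bool)
    rows = []
    for label, mask in (("target", flags.to_numpy()), ("nontarget", ~flags.to_numpy())):
        vals = np.sort(fc[mask].to_numpy())
        frac = np.arange(1, len(vals) + 1) / len(vals) if len(vals) else np.array([])
        rows.append(pd.DataFrame({"stratum": label, "log2fc": vals, "cdf": frac}))
    return pd.concat(rows, ignore_index=True)
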