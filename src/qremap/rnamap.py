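"""Positional motif analysis around regulated exons ("RNA maps").

For exon sets that are activated, repressed or unchanged (background)
under depletion of the RNA-binding protein, the analysis extracts
intronic flanks on both sides of each exon, slides a 50-nt window in
5-nt steps along them, and plots the mean motif (ACUAA) count per
window against the window's position relative to the splice site
(negative = upstream intron).  Windows are labelled by their center so
a profile peak sits at the physical motif position.

The background set provides an empirical 95% confidence band
(bootstrap over exons).  Maximal runs of grid points with a foreground
mean strictly outside the band are candidate peaks; each point in a
peak is tested with a one-sided Mann-Whitney test (foreground counts
greater than background), and the peak's q-value Bonferroni-corrects
the best point p-value twice: once for the number of points in the
peak, once for the number of grid positions on that side.

A complementary 5-mer Fisher enrichment compares total k-mer counts
between foreground and background sequence, Bonferroni-corrected over
all 4^k words.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from qremap.io import AnnotationRecord
from qremap.qre import find_kmer_positions, reverse_complement, _norm

log = logging.getLogger("qremap")

SET_LABELS = ("activated", "repressed", "background")


@dataclass(frozen=True)
class FlankPair:
    """Sense-strand intronic flanks of one exon.

    ``upstream`` ends at the exon's 5' splice-site boundary (its last
    base is adjacent to the exon); ``downstream`` starts at the exon's
    3' boundary.  Either may be shorter than the requested flank when
    the intron is short, or empty for a first/last exon.
    """

    exon_id: str
    set_label: str
    upstream: str
    downstream: str


def extract_flanks(
    exon_sets: pd.DataFrame,
    annotation: list[AnnotationRecord],
    genome: dict[str, str],
    flank_nt: int = 500,
) -> list[FlankPair]:
    """Intronic flanks for each exon row of an exon-set table.

    ``exon_sets`` needs columns chrom, start, end, strand,
    transcript_id, set.  Flanks are truncated at the neighbouring exon
    and reverse-complemented for minus-strand exons so "upstream" is
    always 5' of the exon on the RNA.
    """
    by_tx: dict[str, list[AnnotationRecord]] = {}
    for rec in annotation:
        by_tx.setdefault(rec.transcript_id, []).append(rec)
    pairs: list[FlankPair] = []
    for row in exon_sets.itertuples(index=False):
        recs = sorted(by_tx.get(str(row.transcript_id), []), key=lambda r: r.start)
        idx = next(
            (i for i, r in enumerate(recs) if r.start == row.start and r.end == row.end), None
        )
        if idx is None:
            raise ValueError(
                f"exon {row.chrom}:{row.start}-{row.end} not found in transcript "
                f"{row.transcript_id!r}"
            )
        chrom_seq = genome[str(row.chrom)]
        left_bound = recs[idx - 1].end if idx > 0 else None
        right_bound = recs[idx + 1].start if idx + 1 < len(recs) else None
        left = (
            chrom_seq[max(left_bound, row.start - flank_nt) : row.start]
            if left_bound is not None
            else ""
        )
        right = (
            chrom_seq[row.end : min(right_bound, row.end + flank_nt)]
            if right_bound is not None
            else ""
        )
        if row.strand == "-":
            upstream, downstream = reverse_complement(right), reverse_complement(left)
        else:
            upstream, downstream = left, right
        pairs.append(
            FlankPair(
                exon_id=f"{row.chrom}:{row.start}-{row.end}",
                set_label=str(row.set),
                upstream=upstream,
                downstream=downstream,
            )
        )
    return pairs


def grid_offsets(side: str, flank: int, window: int, step: int) -> np.ndarray:
    """Window-center offsets of the sampling grid on one side.

    Offsets are nt from the splice site, negative on the upstream side.
    A flank of length L holds (L - window)//step + 1 windows.
    """
    n = (flank - window) // step + 1
    if n < 1:
        raise ValueError("flank shorter than one window")
    centers = np.arange(n) * step + window / 2.0
    return -centers[::-1] if side == "up" else centers


def window_counts(
    seqs: list[str], side: str, motif: str, flank: int, window: int, step: int
) -> np.ndarray:
    """Per-sequence motif counts in every grid window (NaN where the flank is short).

    A window counts the motif occurrences that start and end inside it.
    Upstream flanks are anchored at the splice site (their 3' end), so
    grid positions shared between exons with different flank lengths
    line up.
    """
    n_pos = (flank - window) // step + 1
    out = np.full((len(seqs), n_pos), np.nan)
    for i, seq in enumerate(seqs):
        L = min(len(seq), flank)
        if L < window:
            continue
        s = seq[len(seq) - L :] if side == "up" else seq[:L]
        hits = np.asarray(find_kmer_positions(s, motif), dtype=int)
        n_here = (L - window) // step + 1
        if side == "up":
            # window j (grid index counted from the distal end of the full
            # flank) covers s[L - window - k*step : L - k*step) with k the
            # distance in steps from the splice site
            for k in range(n_here):
                lo = L - window - k * step
                hi = L - k * step
                j = n_pos - 1 - k
                out[i, j] = np.sum((hits >= lo) & (hits + len(motif) <= hi))
        else:
            for k in range(n_here):
                lo = k * step
                hi = lo + window
                out[i, k] = np.sum((hits >= lo) & (hits + len(motif) <= hi))
    return out


def windowed_motif_profile(
    counts: np.ndarray, offsets: np.ndarray
) -> pd.DataFrame:
    """Mean motif frequency per grid position with the per-position n.

    Positions where an exon's flank was too short carry NaN in
    ``counts`` and are excluded from that position's mean.
    """
    if counts.size == 0:
        raise ValueError("empty exon set")
    mean, n = _column_means(counts)
    return pd.DataFrame({"position": offsets, "mean_freq": mean, "n": n})


def _column_means(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """NaN-aware per-position mean and n (all-NaN positions give NaN, not a warning)."""
    n = np.sum(~np.isnan(counts), axis=0)
    s = np.nansum(counts, axis=0)
    return np.divide(s, n, out=np.full(n.shape, np.nan, dtype=float), where=n > 0), n


def background_confidence(
    bg_counts: np.ndarray, B: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap 95% confidence band of the background mean frequency.

    Resamples background exons with replacement ``B`` times and takes
    the pointwise 2.5 / 97.5 percentiles of the resampled means.
    """
    if B == 0:
        raise ValueError("B must be positive")
    if B < 100:
        log.warning("bootstrap with B=%d < 100 gives a coarse confidence band", B)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_exons = bg_counts.shape[0]
    idx = rng.integers(0, n_exons, size=(B, n_exons))
    resampled = bg_counts[idx]  # B x n_exons x n_pos
    n = np.sum(~np.isnan(resampled), axis=1)
    s = np.nansum(resampled, axis=1)
    boot = np.divide(s, n, out=np.full(n.shape, np.nan, dtype=float), where=n > 0)
    lo = np.nanpercentile(boot, 2.5, axis=0)
    hi = np.nanpercentile(boot, 97.5, axis=0)
    return lo, hi


@dataclass(frozen=True)
class Peak:
    """A maximal run of grid points outside the background band."""

    side: str  # up | down
    kind: str  # enriched | depleted
    start_pos: float
    end_pos: float
    n_points: int
    p_min: float = float("nan")
    q: float = float("nan")

    @property
    def center(self) -> float:
        return (self.start_pos + self.end_pos) / 2.0


def find_peaks(
    fg_mean: np.ndarray,
    ci_low: np.ndarray,
    ci_high: np.ndarray,
    offsets: np.ndarray,
    side: str,
) -> list[Peak]:
    """Maximal runs of consecutive grid points strictly outside the band.

    Points above ``ci_high`` form enrichment peaks, points below
    ``ci_low`` depletion intervals; a point on the band edge is inside.
    """
    peaks: list[Peak] = []
    for kind, mask in (
        ("enriched", fg_mean > ci_high),
        ("depleted", fg_mean < ci_low),
    ):
        mask = np.asarray(mask) & ~np.isnan(fg_mean)
        i = 0
        while i < len(mask):
            if mask[i]:
                j = i
                while j + 1 < len(mask) and mask[j + 1]:
                    j += 1
                peaks.append(
                    Peak(
                        side=side,
                        kind=kind,
                        start_pos=float(offsets[i]),
                        end_pos=float(offsets[j]),
                        n_points=j - i + 1,
                    )
                )
                i = j + 1
            else:
                i += 1
    return peaks


def peak_qvalues(
    peaks: list[Peak],
    fg_counts: np.ndarray,
    bg_counts: np.ndarray,
    offsets: np.ndarray,
) -> list[Peak]:
    """Attach the per-peak best Mann-Whitney p and the double-Bonferroni q.

    Per grid point inside a peak, a one-sided Mann-Whitney test asks
    whether the foreground per-exon window counts exceed background
    (mirrored for depletion intervals).  ``q = min(1, p_min * n_points
    * n_grid_positions)`` with the grid size of the analysed side.
    """
    n_grid = len(offsets)
    pos_index = {float(o): k for k, o in enumerate(offsets)}
    out = []
    for pk in peaks:
        pvals = []
        i0, i1 = pos_index[pk.start_pos], pos_index[pk.end_pos]
        for k in range(i0, i1 + 1):
            fg = fg_counts[:, k]
            bg = bg_counts[:, k]
            fg, bg = fg[~np.isnan(fg)], bg[~np.isnan(bg)]
            if len(fg) < 2 or len(bg) < 2:
                log.warning("peak point at %s skipped: <2 exons with data", offsets[k])
                continue
            alt = "greater" if pk.kind == "enriched" else "less"
            pvals.append(float(stats.mannwhitneyu(fg, bg, alternative=alt).pvalue))
        if not pvals:
            out.append(pk)
            continue
        p_min = min(pvals)
        q = min(1.0, p_min * pk.n_points * n_grid)
        out.append(replace(pk, p_min=p_min, q=q))
    return out


def count_kmers(seqs: list[str], k: int) -> Counter:
    """Total overlapping k-mer counts over sequences (ACGT words only)."""
    counts: Counter = Counter()
    letters = set("ACGT")
    for seq in seqs:
        s = _norm(seq)
        for i in range(len(s) - k + 1):
            word = s[i : i + k]
            if set(word) <= letters:
                counts[word] += 1
    return counts


def kmer_fisher_enrichment(
    fg_seqs: list[str], bg_seqs: list[str], k: int = 5
) -> pd.DataFrame:
    """Per-k-mer Fisher's exact enrichment of foreground over background.

    The 2x2 table per word is (word count vs all-other-word count,
    foreground vs background); two-sided p-values are
    Bonferroni-corrected over all 4^k words.
    """
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background must be non-empty")
    if any(len(_norm(s)) < k for s in fg_seqs + bg_seqs):
        raise ValueError(f"all sequences must be at least k={k} long")
    fg = count_kmers(fg_seqs, k)
    bg = count_kmers(bg_seqs, k)
    total_fg = sum(fg.values())
    total_bg = sum(bg.values())
    n_words = 4**k
    rows = []
    for word in ("".join(w) for w in itertools.product("ACGT", repeat=k)):
        a, b = fg.get(word, 0), bg.get(word, 0)
        table = [[a, total_fg - a], [b, total_bg - b]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "kmer": word,
                "count_fg": a,
                "count_bg": b,
                "odds": float(odds),
                "p": float(p),
                "p_adj": min(1.0, float(p) * n_words),
            }
        )
    return pd.DataFrame(rows).sort_values(["p", "kmer"], ignore_index=True)


def rna_map(
    flanks: list[FlankPair],
    motif: str = "ACTAA",
    window: int = 50,
    step: int = 5,
    flank: int = 500,
    B: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full positional map: profiles, background band and called peaks.

    Returns ``(profile, peaks)`` data frames.  Peaks are called for
    every non-background set present, separately per side, against the
    background band; peak calling requires a non-empty background set.
    """
    rng = np.random.default_rng(seed)
    sets = sorted({f.set_label for f in flanks})
    if not any(f.set_label == "background" for f in flanks):
        raise ValueError("peak calling needs a background exon set")
    profile_rows = []
    peak_rows = []
    for side in ("up", "down"):
        offsets = grid_offsets(side, flank, window, step)
        seqs_by_set = {
            lab: [f.upstream if side == "up" else f.downstream for f in flanks if f.set_label == lab]
            for lab in sets
        }
        counts_by_set = {
            lab: window_counts(seqs, side, motif, flank, window, step)
            for lab, seqs in seqs_by_set.items()
            if seqs
        }
        bg_counts = counts_by_set["background"]
        ci_low, ci_high = background_confidence(bg_counts, B=B, seed=rng)
        prof = {"side": side, "position": offsets, "bg_ci_low": ci_low, "bg_ci_high": ci_high}
        for lab, counts in counts_by_set.items():
            p = windowed_motif_profile(counts, offsets)
            prof[f"mean_{lab}"] = p["mean_freq"].to_numpy()
            prof[f"n_{lab}"] = p["n"].to_numpy()
        profile_rows.append(pd.DataFrame(prof))
        for lab, counts in counts_by_set.items():
            if lab == "background":
                continue
            fg_mean = _column_means(counts)[0]
            pks = find_peaks(fg_mean, ci_low, ci_high, offsets, side)
            pks = peak_qvalues(pks, counts, bg_counts, offsets)
            for pk in pks:
                peak_rows.append(
                    {
                        "set": lab,
                        "side": pk.side,
                        "kind": pk.kind,
                        "start_pos": pk.start_pos,
                        "end_pos": pk.end_pos,
                        "center": pk.center,
                        "n_points": pk.n_points,
                        "p_min": pk.p_min,
                        "q": pk.q,
                    }
                )
    profile = pd.concat(profile_rows, ignore_index=True)
    peaks = pd.DataFrame(
        peak_rows,
        columns=["set", "side", "kind", "start_pos", "end_pos", "center", "n_points", "p_min", "q"],
    )
    return profile, peaks
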