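"""Splicing-sensitive exon-junction-array statistics.

The chip carries junction probes grouped into probe sets with three
roles per event: ``include`` (junctions specific to the included
isoform), ``skip`` (skipped isoform) and ``constitutive`` (junctions
shared by both, acting as the gene-expression gate).  There are no
mismatch probes, so detection works from an empirical CDF of all probe
intensities, stratified by GC content: a probe's p-value is the
fraction of probes in its GC stratum at least as bright, and a probe
set is "present" when the median probe p-value is at or below the
presence threshold in at least one array.

An alternative splicing event is scored when the gene is expressed
(constitutive set present) and at least two isoform probe sets are
present in any sample.  Scored events are tested with a Kruskal-Wallis
test on include/skip log-ratio probe values grouped by condition, against a
significance cutoff calibrated from Kruskal-Wallis tests on randomly
selected probe sets (the empirical alpha at the 1% quantile of that
null, Bonferroni-divided by the number of null tests).

Two effect sizes are reported with their two published sign
conventions, kept as distinct columns: the Sepscore
(log2 include/skip ratio, experimental over reference; positive = more
inclusion) and the separation score ss (log2 difference of
through-origin regression slopes of skip on include intensity;
negative = more inclusion in the experimental condition).  On
noiseless data ``ss == -sepscore``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("qremap")

SAMPLE_PREFIX = "sample:"
PROBE_COLUMNS = ["probe_id", "probeset_id", "event_id", "role", "gc"]
ROLES = ("include", "skip", "constitutive")
ISOFORM_ROLES = ("include", "skip")


class IntensityError(ValueError):
    """Raised for non-positive probe intensities."""


def sample_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith(SAMPLE_PREFIX)]
    if not cols:
        raise ValueError("probe table has no 'sample:<condition>:<replicate>' columns")
    return cols


def parse_sample(col: str) -> tuple[str, str]:
    """Split ``sample:<condition>:<replicate>`` into (condition, replicate)."""
    m = re.fullmatch(rf"{SAMPLE_PREFIX}([^:]+):([^:]+)", col)
    if not m:
        raise ValueError(f"malformed sample column {col!r}")
    return m.group(1), m.group(2)


def conditions_of(df: pd.DataFrame) -> list[str]:
    seen: list[str] = []
    for c in sample_columns(df):
        cond = parse_sample(c)[0]
        if cond not in seen:
            seen.append(cond)
    return seen


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the mean empirical distribution (rank-wise)."""
    arr = values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    mean_sorted = np.mean(np.take_along_axis(arr, order, axis=0), axis=1)
    out = np.empty_like(arr)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(arr.shape[0])[:, None], axis=0)
    out = mean_sorted[ranks]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_intensities(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize per-array log2 intensities across all arrays.

    Returns a copy of the probe table with the sample columns replaced
    by back-transformed (strictly positive) normalized intensities.
    """
    cols = sample_columns(df)
    vals = df[cols].to_numpy(dtype=float)
    if not np.all(vals > 0):
        bad = df.loc[(vals <= 0).any(axis=1), "probe_id"].iloc[0]
        raise IntensityError(f"non-positive intensity for probe {bad!r}")
    normed = quantile_normalize(pd.DataFrame(np.log2(vals), index=df.index, columns=cols))
    out = df.copy()
    out[cols] = np.exp2(normed.to_numpy())
    return out


def gc_strata(gc: pd.Series, gc_bins: int = 10, min_stratum: int = 20) -> pd.Series:
    """Assign probes to GC quantile strata, merging strata under ``min_stratum``."""
    if not gc.between(0, 1).all():
        raise ValueError("gc must lie in [0,1]")
    codes = pd.qcut(gc.rank(method="first"), min(gc_bins, len(gc)), labels=False)
    codes = pd.Series(np.asarray(codes, dtype=int), index=gc.index)
    sizes = codes.value_counts().sort_index()
    # accumulate neighbouring GC bins until each stratum holds >= min_stratum
    groups: list[list[int]] = []
    cur: list[int] = []
    cur_n = 0
    for lab, n in sizes.items():
        cur.append(int(lab))
        cur_n += int(n)
        if cur_n >= min_stratum:
            groups.append(cur)
            cur, cur_n = [], 0
    if cur:
        if groups:
            groups[-1].extend(cur)
        else:
            groups.append(cur)
    remap = {lab: gi for gi, grp in enumerate(groups) for lab in grp}
    return codes.map(remap)


def empirical_probe_pvalue(
    df: pd.DataFrame, gc_bins: int = 10, min_stratum: int = 20
) -> pd.DataFrame:
    """Per-probe, per-array empirical p-value against the GC-stratified background.

    Within a stratum, ``p = #(probes with intensity >= x) / stratum
    size`` so the brightest probe gets ``1/n`` and the dimmest 1.0;
    p-values are valid (never 0).
    """
    cols = sample_columns(df)
    strata = gc_strata(df["gc"], gc_bins=gc_bins, min_stratum=min_stratum)
    pvals = pd.DataFrame(np.nan, index=df.index, columns=cols)
    for _, idx in strata.groupby(strata).groups.items():
        n = len(idx)
        block = df.loc[idx, cols].to_numpy(dtype=float)
        for j in range(block.shape[1]):
            x = block[:, j]
            srt = np.sort(x)
            n_ge = n - np.searchsorted(srt, x, side="left")
            pvals.loc[idx, cols[j]] = n_ge / n
    return pvals


def probeset_presence(
    pvals: pd.DataFrame, probeset_ids: pd.Series, presence_p: float = 0.05
) -> pd.Series:
    """Present <=> the median probe p-value is <= ``presence_p`` in >= 1 array."""
    med = pvals.groupby(probeset_ids).median()
    return (med <= presence_p).any(axis=1)


def detect_event(roles: pd.Series, present: pd.Series) -> bool:
    """Score an event: gene expressed and >= 2 isoform probe sets present.

    ``roles`` maps probeset_id -> role for one event; ``present`` maps
    probeset_id -> presence call.  Events with fewer than two isoform
    probe sets are skipped (logged) and return False.
    """
    iso = [ps for ps, r in roles.items() if r in ISOFORM_ROLES]
    const = [ps for ps, r in roles.items() if r == "constitutive"]
    if len(iso) < 2:
        log.warning("event with <2 isoform probe sets skipped")
        return False
    expressed = any(bool(present.get(ps, False)) for ps in const)
    n_iso_present = sum(bool(present.get(ps, False)) for ps in iso)
    return expressed and n_iso_present >= 2


def kruskal_pvalue(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (df = groups-1).

    All values tied across all groups gives H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("Kruskal-Wallis needs >= 2 groups of >= 2 values")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    if h <= 0 or np.isnan(p):
        # the tie correction can drive H a hair below 0 in floating point
        return 0.0, 1.0
    return float(h), float(p)


def include_skip_ratios(event_df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per condition, the include/skip-normalized probe values for the KW test.

    For every (include probe, skip probe) pair and every array, the
    value is the log2 include/skip intensity ratio; values are pooled
    per condition.  Ratios carry the full inclusion-odds effect (a
    splicing swap moves include up and skip down, so the ratio moves
    twice), and a pure expression change cancels entirely.  The values
    of one condition are mutually dependent (pairs share probes), which
    is exactly why significance is judged against an empirical null of
    the same statistic rather than the nominal chi-square tail.
    """
    cols = sample_columns(event_df)
    inc = event_df[event_df["role"] == "include"]
    skp = event_df[event_df["role"] == "skip"]
    if inc.empty or skp.empty:
        raise ValueError("event needs both include and skip probes")
    li = np.log2(inc[cols].to_numpy(dtype=float))  # n_inc x n_arrays
    ls = np.log2(skp[cols].to_numpy(dtype=float))  # n_skp x n_arrays
    pairs = li[:, None, :] - ls[None, :, :]  # n_inc x n_skp x n_arrays
    conds = np.array([parse_sample(c)[0] for c in cols])
    return {c: pairs[:, :, conds == c].ravel() for c in pd.unique(conds)}


def kw_event_test(event_df: pd.DataFrame) -> float:
    """Kruskal-Wallis p-value that an event's probe values are condition-independent."""
    groups = include_skip_ratios(event_df)
    return kruskal_pvalue(list(groups.values()))[1]


@dataclass(frozen=True)
class AlphaCalibration:
    """Empirical significance calibration for the event-level KW test."""

    n_tests: int
    quantile: float
    empirical_alpha: float
    bonferroni_cutoff: float

    def __post_init__(self) -> None:
        if not 0 < self.empirical_alpha < 1:
            raise ValueError(f"empirical_alpha outside (0,1): {self.empirical_alpha}")

    @classmethod
    def from_alpha(cls, empirical_alpha: float, n_tests: int, quantile: float = 0.01):
        if n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        return cls(
            n_tests=n_tests,
            quantile=quantile,
            empirical_alpha=empirical_alpha,
            bonferroni_cutoff=empirical_alpha / n_tests,
        )


def calibrate_alpha(
    null_pvalues: np.ndarray, quantile: float = 0.01, n_tests: int | None = None
) -> AlphaCalibration:
    """Empirical alpha = the ``quantile`` order statistic of null KW p-values.

    The Bonferroni cutoff divides that alpha by the number of tests.
    """
    p = np.asarray(null_pvalues, dtype=float)
    if n_tests is None:
        n_tests = p.size
    if p.size < 100:
        raise ValueError("need at least 100 null p-values for calibration")
    alpha = float(np.quantile(p, quantile))
    return AlphaCalibration.from_alpha(alpha, n_tests=n_tests, quantile=quantile)


def null_kw_pvalues(
    df: pd.DataFrame,
    n_tests: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """KW p-values of the event statistic on randomly selected probe sets.

    Each test draws a random event from the table (with replacement)
    and applies the identical Kruskal-Wallis machinery to its isoform
    probe sets.  Because the overwhelming majority of probe sets on a
    chip carry no condition effect, the resulting p-values sample the
    test's null distribution with the same per-array correlation
    structure as the real event tests — which is the point of the
    empirical (rather than nominal chi-square) alpha.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    iso = df[df["role"].isin(ISOFORM_ROLES)]
    groups = {eid: ev for eid, ev in iso.groupby("event_id", sort=True)}
    event_ids = sorted(groups)
    if not event_ids:
        raise ValueError("no events with isoform probes in the table")
    cache: dict[str, float] = {}
    out = np.empty(n_tests)
    for t in range(n_tests):
        eid = event_ids[int(rng.integers(0, len(event_ids)))]
        if eid not in cache:
            cache[eid] = kw_event_test(groups[eid])
        out[t] = cache[eid]
    return out


def sepscore(inc_exp: float, skip_exp: float, inc_ref: float, skip_ref: float) -> float:
    """log2 of the include/skip ratio, experimental over reference.

    Positive values mean more exon inclusion in the experimental sample.
    """
    for name, v in (("inc_exp", inc_exp), ("skip_exp", skip_exp),
                    ("inc_ref", inc_ref), ("skip_ref", skip_ref)):
        if v <= 0:
            raise IntensityError(f"{name} must be positive, got {v}")
    return float(np.log2((inc_exp / skip_exp) / (inc_ref / skip_ref)))


def _origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points per condition for the origin-constrained fit")
    denom = float(np.sum(x * x))
    if denom == 0:
        raise ValueError("include intensities are all zero")
    return float(np.sum(x * y) / denom)


def separation_score(
    inc_exp: np.ndarray, skip_exp: np.ndarray, inc_ref: np.ndarray, skip_ref: np.ndarray
) -> float:
    """log2 difference of skip-on-include regression slopes (through the origin).

    Per condition the slope is ``b = sum(x*y)/sum(x^2)`` with x the
    include and y the skip intensities of paired points;
    ``ss = log2(b_exp) - log2(b_ref)``.  Negative ss means relatively
    more inclusion in the experimental condition.
    """
    b_exp = _origin_slope(inc_exp, skip_exp)
    b_ref = _origin_slope(inc_ref, skip_ref)
    if b_exp <= 0 or b_ref <= 0:
        raise ValueError(f"non-positive slope (b_exp={b_exp}, b_ref={b_ref})")
    return float(np.log2(b_exp) - np.log2(b_ref))


def ss_to_fold(ss: float) -> float:
    """Fold change in inclusion implied by a separation score.

    The magnitude is ``2**|ss|``; the sign of ``ss`` gives the
    direction (negative = more inclusion in the experimental
    condition), e.g. ss = -1.72 means 2**1.72 = 3.3-fold more
    inclusion.
    """
    return float(2.0 ** abs(ss))


def _set_summaries(event_df: pd.DataFrame, cols: list[str]) -> dict[str, pd.DataFrame]:
    """Per role, the per-array probe-set summary (median normalized intensity)."""
    out = {}
    for role in ("include", "skip"):
        sub = event_df[event_df["role"] == role]
        out[role] = sub[cols].median(axis=0)
    return out


def analyze_events(
    df: pd.DataFrame,
    reference: str,
    presence_p: float = 0.05,
    gc_bins: int = 10,
    calibration: AlphaCalibration | None = None,
) -> pd.DataFrame:
    """Full junction-array event analysis for a two-condition experiment.

    Normalizes intensities, makes presence calls, scores events, runs
    the per-event Kruskal-Wallis test and computes Sepscore and
    separation score (experimental condition = the non-reference one).
    ``significant`` is filled only when a calibration is supplied.
    """
    conds = conditions_of(df)
    if reference not in conds:
        raise ValueError(f"reference condition {reference!r} not among {conds}")
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    exp_cond = next(c for c in conds if c != reference)

    normed = normalize_intensities(df)
    cols = sample_columns(normed)
    pvals = empirical_probe_pvalue(normed, gc_bins=gc_bins)
    present = probeset_presence(pvals, normed["probeset_id"], presence_p=presence_p)

    ref_cols = [c for c in cols if parse_sample(c)[0] == reference]
    exp_cols = [c for c in cols if parse_sample(c)[0] == exp_cond]

    rows = []
    for event_id, ev in normed.groupby("event_id", sort=True):
        roles = ev.drop_duplicates("probeset_id").set_index("probeset_id")["role"]
        detected = detect_event(roles, present)
        ev_iso = ev[ev["role"].isin(ISOFORM_ROLES)]
        kw_p = kw_event_test(ev_iso)
        summ = _set_summaries(ev_iso, cols)
        inc, skp = summ["include"], summ["skip"]
        sep = sepscore(
            float(inc[exp_cols].median()),
            float(skp[exp_cols].median()),
            float(inc[ref_cols].median()),
            float(skp[ref_cols].median()),
        )
        ss = separation_score(
            inc[exp_cols].to_numpy(),
            skp[exp_cols].to_numpy(),
            inc[ref_cols].to_numpy(),
            skp[ref_cols].to_numpy(),
        )
        rows.append(
            {
                "event_id": event_id,
                "event_type": ev["event_type"].iloc[0] if "event_type" in ev else "CE",
                "detected": detected,
                "kw_p": kw_p,
                "significant": (
                    bool(kw_p < calibration.bonferroni_cutoff) if calibration else pd.NA
                ),
                "sepscore": sep,
                "ss": ss,
            }
        )
    return pd.DataFrame(rows)
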