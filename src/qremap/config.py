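"""Run configuration: every tunable constant of the pipeline in one place.

The defaults are the values used throughout the analysis: 50-nt windows
slid in 5-nt steps for RNA maps, a minimal +/-1.5-fold expression change,
a summed-CPM expression floor of 1, a probe-set presence threshold of
0.05, 12,740 null Kruskal-Wallis tests for alpha calibration, GC deciles
for probe stratification and 1,000 bootstrap replicates for the
background confidence band.  A flat YAML file can override any of them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    #: k-mer length for word enrichment (ACUAA analyses use k=5)
    k: int = 5
    #: sliding-window width, nt
    window: int = 50
    #: sliding-window sampling interval, nt
    step: int = 5
    #: intronic flank length extracted on each side of an exon, nt
    flank: int = 500
    #: minimal fold change called differential (inclusive)
    fold_cutoff: float = 1.5
    #: expression floor: sum of the two conditions' CPM (inclusive)
    cpm_sum_cutoff: float = 1.0
    #: probe-set presence threshold on the median empirical probe p-value
    presence_p: float = 0.05
    #: q-value cutoff for differential calls in array mode
    q_cutoff: float = 0.05
    #: number of Kruskal-Wallis tests on random probe sets for calibration
    n_null_tests: int = 12740
    #: quantile of the null p-values that defines the empirical alpha
    alpha_quantile: float = 0.01
    #: number of GC strata (quantile bins) for empirical probe p-values
    gc_bins: int = 10
    #: bootstrap replicates for the background confidence band
    bootstrap_B: int = 1000
    #: first position of the QRE upstream half-site: "U" (strict) or "N"
    first_pos: str = "U"
    #: QRE enumeration: "greedy" (non-overlapping) or "all" pairings
    pairing: str = "greedy"

    def __post_init__(self) -> None:
        if not (self.window >= self.step >= 1):
            raise ValueError(f"require window >= step >= 1, got {self.window}, {self.step}")
        for name in ("presence_p", "q_cutoff", "alpha_quantile"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if self.fold_cutoff <= 1:
            raise ValueError(f"fold_cutoff must exceed 1, got {self.fold_cutoff}")
        if self.k < 1 or self.gc_bins < 1 or self.bootstrap_B < 0:
            raise ValueError("k and gc_bins must be >= 1, bootstrap_B >= 0")
        if self.first_pos not in ("U", "N"):
            raise ValueError(f"first_pos must be 'U' or 'N', got {self.first_pos!r}")
        if self.pairing not in ("greedy", "all"):
            raise ValueError(f"pairing must be 'greedy' or 'all', got {self.pairing!r}")
        if self.flank < self.window:
            raise ValueError("flank must be at least one window long")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a flat key-value YAML file; unknown keys are rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {', '.join(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def as_dict(self) -> dict:
        return asdict(self)
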