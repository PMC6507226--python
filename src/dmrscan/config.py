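"""Run configuration for the whole pipeline.

Every tunable threshold of the analysis lives in one dataclass so that a
run is fully described by a single small file.  Defaults follow the
standard sliding-window protocol: 1-kb windows advanced in 100-bp steps,
windows kept only when they contain more than ``min_c_sites`` cytosine
sites, and a window is a candidate DMR when the pooled methylation-level
ratio exceeds ``min_fold_change``, the absolute level difference exceeds
``min_abs_diff`` and the two-sided Fisher p-value is below ``alpha_raw``;
Benjamini-Hochberg q-values are then thresholded at ``alpha_fdr``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    window_size_bp: int = 1000
    step_bp: int = 100
    #: windows qualify only with strictly more than this many cytosine sites
    min_c_sites: int = 10
    min_fold_change: float = 2.0
    min_abs_diff: float = 0.1
    alpha_raw: float = 0.05
    alpha_fdr: float = 0.05
    promoter_bp: int = 2000
    kmer_len: int = 9
    n_permutations: int = 25
    rng_seed: int = 0
    min_site_coverage: int = 4
    site_call_alpha: float = 0.05
    #: scan all contexts jointly ("joint") or one of CG/CHG/CHH
    scan_context: str = "joint"
    #: collapse symmetric CpG strand pairs into one site when calling
    collapse_cpg_strands: bool = False
    #: rounding mode for reported percentages: "half_up" or "truncate"
    percent_rounding: str = "half_up"

    def __post_init__(self) -> None:
        for name in ("window_size_bp", "step_bp", "min_c_sites",
                     "min_fold_change", "min_abs_diff", "alpha_raw",
                     "alpha_fdr", "promoter_bp", "kmer_len",
                     "n_permutations", "min_site_coverage",
                     "site_call_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.step_bp > self.window_size_bp:
            raise ValueError("step_bp must not exceed window_size_bp")
        if self.kmer_len % 2 == 0:
            raise ValueError("kmer_len must be odd")
        if self.scan_context not in ("joint", "CG", "CHG", "CHH"):
            raise ValueError(f"unknown scan_context {self.scan_context!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from a YAML (or plain key: value) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
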