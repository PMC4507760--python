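"""Analysis configuration: every threshold the pipeline applies, in one place.

Defaults reproduce the published criteria: |r| >= 0.9 with p <= 0.05 for edge
retention, a 2-fold differential cutoff, the early (0.5-4 h) / late (6-24 h)
response windows split at the onset of TAG accumulation, and the top-5%
degree rule for hubs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class AnalysisConfig:
    #: minimum correlation magnitude for a retained edge
    r_min: float = 0.9
    #: maximum (raw, uncorrected) two-sided p-value for a retained edge
    p_max: float = 0.05
    #: fold-change cutoff for calling an entity differential (symmetric in
    #: log space: down means fc <= 1/fc_threshold)
    fc_threshold: float = 2.0
    #: early-response window, half-open (lo, hi] hours
    bts_window: tuple[float, float] = (0.0, 4.0)
    #: late-response window, closed [lo, hi] hours
    ats_window: tuple[float, float] = (6.0, 24.0)
    #: time points (inclusive bounds, hours) used for correlation; the
    #: default excludes the optional 48 h point
    correlation_window: tuple[float, float] = (0.5, 24.0)
    #: allowed lags in sample steps (index space, regulator leading for +1)
    lag_set: tuple[int, ...] = (0, 1)
    #: fraction of TF nodes kept as hub candidates (top 5%)
    hub_fraction: float = 0.05
    #: minimum paired points for a correlation to be evaluated
    min_overlap: int = 5
    #: "target": edge phase follows the target's onset window (permits the
    #: permanent hub class); "strict": both endpoints must share a window
    phase_mode: str = "target"
    #: "any": hub must be top-5% in the whole network and >=1 subnetwork;
    #: "all": in every subnetwork where it has degree >= 1
    hub_subnetwork_rule: str = "any"
    #: p-value method: "t" (t transform) or "permutation" (seeded shuffles)
    p_method: str = "t"
    n_permutations: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_min <= 1):
            raise ValueError("r_min must be in (0, 1]")
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must be in (0, 1)")
        if not (0 < self.hub_fraction < 1):
            raise ValueError("hub_fraction must be in (0, 1)")
        if self.min_overlap < 3:
            raise ValueError("min_overlap must be >= 3")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if self.bts_window[1] >= self.ats_window[0]:
            raise ValueError("bts_window and ats_window must be disjoint")
        if self.phase_mode not in ("target", "strict"):
            raise ValueError("phase_mode must be 'target' or 'strict'")
        if self.hub_subnetwork_rule not in ("any", "all"):
            raise ValueError("hub_subnetwork_rule must be 'any' or 'all'")
        if self.p_method not in ("t", "permutation"):
            raise ValueError("p_method must be 't' or 'permutation'")
        self.bts_window = tuple(self.bts_window)
        self.ats_window = tuple(self.ats_window)
        self.correlation_window = tuple(self.correlation_window)
        self.lag_set = tuple(self.lag_set)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        # YAML has no tuple type; coerce list-valued fields back
        for key in ("bts_window", "ats_window", "correlation_window", "lag_set"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls.from_dict(d)
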