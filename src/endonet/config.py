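"""Run configuration: every stage parameter in one validated, hashable place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml


@dataclass
class RunConfig:
    """Parameters for the full pipeline; serialized into every output."""

    # trace processing
    fs: float = 10.0
    baseline_window: tuple = (0.0, 60.0)
    threshold_sd_mult: float = 5.0
    responder_fraction: float = 0.25
    skip_seconds: float = 0.0
    # cross-correlation
    window_len: float = 60.0
    n_windows: int = 2
    max_lag: float = 2.5
    lag_step: float = 0.1
    # null / references / permutations
    null_n_iter: int = 100
    null_aggregation: str = "pooled"
    reference_n_iter: int = 100
    permutation_n_perm: int = 1000
    # wave analysis
    k_sd: float = 3.0
    shortcut_mode: str = "residual"
    # geometry
    hull_ratio: float = 0.2
    contact_tolerance: float = 1e-9
    # randomness
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 < self.responder_fraction <= 1:
            raise ValueError("responder_fraction must be in (0, 1]")
        if self.skip_seconds < 0:
            raise ValueError("skip_seconds must be >= 0")
        if self.null_aggregation not in ("pooled", "mean_of_iterations"):
            raise ValueError("unknown null_aggregation")
        if min(self.null_n_iter, self.reference_n_iter,
               self.permutation_n_perm, self.n_windows) < 1:
            raise ValueError("iteration counts must be >= 1")
        stride = self.fs * self.lag_step
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError("fs * lag_step must be a positive integer")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_window"] = list(self.baseline_window)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "baseline_window" in data:
            data["baseline_window"] = tuple(data["baseline_window"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def spawn_seeds(self, n: int = 6) -> list:
        """Derive independent per-stage integer seeds (< 2**31) from the
        root seed."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s) for s in ss.generate_state(n) % (2 ** 31)]
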