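"""Run configuration and reproducible random substreams.

All randomness in a run flows from a single integer seed through named
substreams, so each component (stimulus draws, goal sequence, agent
choices, pose synthesis, ABR synthesis) is independently reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: Fixed substream indices; adding names must never renumber existing ones.
STREAMS = {"stimulus": 0, "goals": 1, "agent": 2, "pose": 3, "abr": 4, "startle": 5}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named component of a seeded run."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), STREAMS[name]]))


@dataclass
class RunConfig:
    """Resolved parameters of one simulation/analysis run."""
    seed: int = 0
    # arena
    side_length: float = 15.0
    entry_width: float = 5.0
    long_diagonal: float = 40.0
    px_per_cm: float = 1.0
    # stimulus
    stim_mode: str = "fixed"          # 'fixed' | 'variable'
    # agent
    preset: str = "expert"
    n_trials: int = 500
    # analysis thresholds
    criterion_ports_poked: float = 2.5
    smoothing_sd_trials: float = 50.0
    debounce_frames: int = 2
    min_center_frames: int = 3
    still_threshold_cm_s: float = 0.5
    abr_n_taps: int = 32
    abr_cutoff_hz: float = 100.0
    abr_reject_pct: float = 5.0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)
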