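"""Run configuration: every tunable of the pipeline with its default.

Defaults are the workflow's standard settings: scan minimum score 15 with
mismatch penalty 5; 300-bp flanks; repeat number > 7; primer Tm window
58-62 degC with pair difference < 4 degC; 3' distance > 10 bp; test alpha
0.05; assignment Q threshold 0.60; panel size 8. CLI flags override config
file values, which override these defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # scan
    min_score: int = 15
    mismatch_penalty: int = 5
    motif_lengths: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    # candidate filter
    flank: int = 300
    min_repeats_exclusive: int = 7  # repeat number must exceed this
    primer_min_tm: float = 58.0
    primer_max_tm: float = 62.0
    primer_max_tm_diff: float = 4.0
    min_3prime_distance: int = 10
    # popgen
    alpha: float = 0.05
    hwe_reps: int = 100_000
    ld_reps: int = 10_000
    seed: int = 0
    # panels
    panel_size: int = 8
    q_threshold: float = 0.60

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            data.update(yaml.safe_load(Path(path).read_text()) or {})
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def dump(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)
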