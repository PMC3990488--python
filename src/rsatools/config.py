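"""Run configuration: seeds, method defaults, and decision thresholds.

Serializes round-trip losslessly to JSON; every stochastic operation run
through the CLI reads its seed from here.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

from .inference import MIN_CONDITIONS_RANDOMIZATION, MIN_SUBJECTS_SIGNED_RANK

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    method: str = "kendall_tau_a"
    dissimilarity: str = "correlation"
    mc_procedure: str = "fdr_bh"
    alpha: float = 0.05
    n_permutations: int = 10_000
    n_bootstrap: int = 1_000
    min_subjects_signed_rank: int = MIN_SUBJECTS_SIGNED_RANK
    min_conditions_randomization: int = MIN_CONDITIONS_RANDOMIZATION
    output_dir: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        return cls.from_json(Path(path).read_text())
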