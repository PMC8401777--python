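"""Run configuration: every tunable constant of the pipeline in one place."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass


@dataclass
class RunConfig:
    """Serializable pipeline configuration.

    Defaults are the working constants of the method: the cliff /
    non-cliff potency thresholds (2 and 1 log units), the fragment size
    constraints (substituents of at most 13 heavy atoms differing by at
    most 8), the kept fingerprint bond diameters (2 and 4) and the SVM
    C grid searched by five-fold cross-validation.
    """

    seed: int = 0
    C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
    ac_threshold: float = 2.0
    non_ac_threshold: float = 1.0
    max_sub_atoms: int = 13
    max_sub_diff: int = 8
    fingerprint_diameters: tuple[int, ...] = (2, 4)
    shap_samples: int = 2048
    shap_feature_cap: int = 64
    output_dir: str = "mmpcliff_out"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        for key in ("C_grid", "fingerprint_diameters"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
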