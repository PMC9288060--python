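"""Run configuration: every tunable threshold with its study default."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline parameters in one validated, serializable object.

    Defaults are the study constants where stated (5 support reads, 50 kb
    gene window, 3 bp splice distance, 0.85 barcode identity, p cutoffs
    0.05 / 0.0001 / 0.01, single-cell |logFC| 0.25) and this package's
    documented choices elsewhere (j_min, identity thresholds).
    """

    # reference construction
    window: int = 50_000
    stranded_l1: bool = False
    # detection
    read_length: int = 100
    min_support: int = 5
    j_min: int = 10
    min_fragment: int = 18
    support_identity: float = 0.95
    clip_threshold: int = 20
    splice_distance: int = 3
    # cohort statistics
    p_differential: float = 0.05
    p_correlation: float = 1e-4
    # single cell
    barcode_identity: float = 0.85
    sc_p: float = 0.01
    sc_lfc: float = 0.25
    chemistry: str = "tenx_v2"
    # bookkeeping
    seed: int = 0
    outdir: str = "."

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if not 0 < self.support_identity <= 1:
            raise ValueError("support_identity must be in (0, 1]")
        if not 0 < self.barcode_identity < 1:
            raise ValueError("barcode_identity must be in (0, 1)")
        for name in ("p_differential", "p_correlation", "sc_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.j_min < 1 or self.min_fragment < 1 or self.read_length < 2 * self.j_min:
            raise ValueError("inconsistent read_length / j_min / min_fragment")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def asdict(self) -> dict:
        return asdict(self)
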