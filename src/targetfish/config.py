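"""Pipeline configuration: every tunable decision in one YAML-able object."""
from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


@dataclasses.dataclass
class PipelineConfig:
    """Knobs for the full inverse-screening pipeline.

    Attributes
    ----------
    similarity_cutoff
        Minimum Tanimoto (inclusive) for a ligand-based hit.
    fingerprint_radius, fingerprint_bits
        Morgan fingerprint parameters (ECFP4-like defaults).
    z_weights
        (wT, wL) for Zcomb; must sum to 1.
    z_orientation
        ``per_target`` (ZT standardizes within a target column) or
        ``per_ligand`` (transposed convention).
    threshold_inclusive
        Whether V = M + 3*sigma itself is admissible in method I.
    zcomb_cutoff
        Optional upper bound on the winning Zcomb (None = no cutoff).
    exclusion_policy, exclusion_list, exclusion_k
        Promiscuous-target handling: ``manual`` uses ``exclusion_list``;
        ``automatic`` flags counts above median + k*MAD.
    fuse_runs
        Count each approach once across the with/without-exclusion runs.
    """

    similarity_cutoff: float = 0.75
    fingerprint_radius: int = 2
    fingerprint_bits: int = 2048
    z_weights: tuple[float, float] = (0.7, 0.3)
    z_orientation: str = "per_target"
    threshold_inclusive: bool = True
    zcomb_cutoff: float | None = None
    exclusion_policy: str = "automatic"
    exclusion_list: list[str] = dataclasses.field(default_factory=list)
    exclusion_k: float = 5.0
    fuse_runs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        if "z_weights" in data:
            data["z_weights"] = tuple(data["z_weights"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["z_weights"] = list(data["z_weights"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
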