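"""Run configuration for the colonization analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Day windows of the three colonization stages (inclusive bounds):
#: initial colonization, community formation, primary succession.
DEFAULT_STAGE_RANGES: dict[str, tuple[int, int]] = {
    "T1": (3, 6),
    "T2": (12, 18),
    "T3": (24, 27),
}

UNASSIGNED = "unassigned"


@dataclass
class AnalysisConfig:
    """Tunable knobs of the niche / diversity analysis.

    Parameters
    ----------
    dominance_threshold
        Species with dominance index ``Di >= dominance_threshold`` are
        classified dominant (McNaughton convention; ties are dominant).
    delta_o_mode
        How the resource-occupancy change ``dOi`` is derived from the
        directed overlap matrix. Only ``"directed"`` is built in.
    ri_mode
        ``"product"``: Ri = Bi * dOi (total); ``"ratio"``: Ri = Bi / dOi,
        undefined where dOi == 0.
    stage_ranges
        Inclusive day windows per stage label; days outside every window
        are left unassigned.
    permutations
        Number of label permutations for PERMANOVA / PERMDISP / ANOSIM / RDA.
    seed
        Seed for every random draw in the run.
    rare_rel_abundance, rare_frequency
        A taxon is pooled into "Other" for reporting when its stage-level
        relative abundance is below the first threshold AND its occurrence
        frequency is below the second.
    epsilon
        Additive constant in the normalized dissimilarities
        ``Xd = Bray / (Bray_max + epsilon)`` and the Euclidean analogue.
    bray_relative
        Compute Bray–Curtis on per-sample relative abundances instead of
        raw counts.
    env_standardize
        z-score environmental variables before Euclidean distances / RDA.
    """

    dominance_threshold: float = 0.02
    delta_o_mode: str = "directed"
    ri_mode: str = "product"
    stage_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_RANGES)
    )
    permutations: int = 999
    seed: int = 0
    rare_rel_abundance: float = 0.001
    rare_frequency: float = 0.01
    epsilon: float = 0.001
    bray_relative: bool = False
    env_standardize: bool = True

    def __post_init__(self) -> None:
        for name in ("dominance_threshold", "rare_rel_abundance", "rare_frequency"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.permutations < 99:
            raise ValueError(f"permutations must be >= 99, got {self.permutations}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.delta_o_mode not in ("directed", "custom"):
            raise ValueError(f"unknown delta_o_mode {self.delta_o_mode!r}")
        if self.ri_mode not in ("product", "ratio"):
            raise ValueError(f"unknown ri_mode {self.ri_mode!r}")
        ranges = {k: (int(lo), int(hi)) for k, (lo, hi) in self.stage_ranges.items()}
        for label, (lo, hi) in ranges.items():
            if lo > hi:
                raise ValueError(f"stage {label}: empty day range ({lo}, {hi})")
        labels = sorted(ranges)
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                (a0, a1), (b0, b1) = ranges[la], ranges[lb]
                if a0 <= b1 and b0 <= a1:
                    raise ValueError(f"stage ranges {la} and {lb} overlap")
        self.stage_ranges = ranges

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stage_ranges" in raw:
            raw["stage_ranges"] = {
                k: tuple(v) for k, v in raw["stage_ranges"].items()
            }
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_ranges"] = {k: list(v) for k, v in self.stage_ranges.items()}
        return d
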