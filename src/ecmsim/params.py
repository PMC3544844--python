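"""Phenotype parameter sets and the probability model.

A :class:`Phenotype` collects the cell-line-level parameters (maximum
deposition/degradation probabilities, the no-action probability, the
fiber-count thresholds gating deposition and motility, and cell counts).  Two
presets encode a lowly invasive (LNCaP-like) and a highly invasive
(DU-145-like) model cell line.

A :class:`ProbabilityModel` collects the shape parameters of the probability
functions (logistic midpoints/steepness for degradation and deposition, the
Gaussian motility curve, the pull-versus-degrade bias during migration,
steric and retry limits).  These shapes are not pinned down by any published
table; the defaults here were obtained once by the same systematic
grid-and-refine fitting procedure the quantification module exposes, scored
against the qualitative remodeling behaviour the model is meant to show (see
docs/methods.md), and are fully config-exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

__all__ = [
    "Phenotype",
    "ProbabilityModel",
    "LOW_INVASIVE",
    "HIGH_INVASIVE",
    "PHENOTYPE_PRESETS",
    "MATRIX_PRESETS",
    "phenotype_from_dict",
]


@dataclass(frozen=True)
class Phenotype:
    """Cell-line parameter set.

    ``p_dep_max`` / ``p_deg_max`` are the saturating maxima of the deposition
    and degradation probabilities; ``p_nothing`` the per-close-fiber
    no-action probability (realignment gets the remainder,
    ``P_align = 1 - P_nothing - P_degrade``).  ``deposit_threshold`` is the
    close-fiber count at or above which deposition is forbidden;
    ``motility_threshold`` the count at or above which movement is forbidden.
    """

    name: str = "custom"
    p_dep_max: float = 0.8
    p_deg_max: float = 0.1
    p_nothing: float = 0.9
    deposit_threshold: int = 20
    motility_threshold: int = 35
    initial_cells: int = 15
    min_cells: int = 14

    def __post_init__(self) -> None:
        for attr in ("p_dep_max", "p_deg_max", "p_nothing"):
            v = getattr(self, attr)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{attr} must be a probability, got {v}")
        if self.p_nothing + self.p_deg_max > 1.0 + 1e-12:
            raise ValueError(
                "p_nothing + p_deg_max must not exceed 1 (P_align would go negative)"
            )
        if self.deposit_threshold <= 0 or self.motility_threshold <= 0:
            raise ValueError("thresholds must be positive integers")
        if self.min_cells < 0 or self.initial_cells < 0:
            raise ValueError("cell counts must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def with_overrides(self, **kwargs) -> "Phenotype":
        return replace(self, **kwargs)


LOW_INVASIVE = Phenotype(
    name="low_invasive",
    p_dep_max=0.8,
    p_deg_max=0.1,
    p_nothing=0.9,
    deposit_threshold=20,
    motility_threshold=35,
    initial_cells=15,
    min_cells=14,
)

HIGH_INVASIVE = Phenotype(
    name="high_invasive",
    p_dep_max=0.8,
    p_deg_max=0.2,
    p_nothing=0.8,
    deposit_threshold=20,
    motility_threshold=50,
    initial_cells=15,
    min_cells=14,
)

PHENOTYPE_PRESETS = {p.name: p for p in (LOW_INVASIVE, HIGH_INVASIVE)}

#: Fiber counts emulating collagen gels of a given concentration.
MATRIX_PRESETS = {"2mgml": 1200, "3mgml": 2000, "4mgml": 3000, "4.5mgml": 3500}


def phenotype_from_dict(data: dict) -> Phenotype:
    """Build a phenotype from a plain dict, starting from a preset if named."""
    data = dict(data)
    name = data.pop("name", None)
    if name in PHENOTYPE_PRESETS:
        return PHENOTYPE_PRESETS[name].with_overrides(**data)
    return Phenotype(name=name or "custom", **data)


@dataclass(frozen=True)
class ProbabilityModel:
    """Shape parameters of the per-cell probability functions.

    Degradation probability: ``p_deg_max / (1 + exp(-k_deg*(closeF - x0_deg)))``
    (increasing in closeF).  Deposition: ``p_dep_max / (1 + exp(+k_dep*(closeF
    - x0_dep)))`` (decreasing), consulted only below the deposit threshold.
    Movement: Gaussian in closeF with hard zero at the motility threshold;
    when ``move_mu``/``move_sigma`` are None they scale with the phenotype's
    motility threshold via ``move_mu_scale``/``move_sigma_scale`` so a more
    motile phenotype keeps moving at higher local density.

    ``close_radius`` (um) defines "close" fibers, 1.5x the 9 um cell radius by
    default; ``max_step`` is the per-step movement bound, 2 lattice units =
    9 um by default.
    """

    logistic_k_deg: float = 3.0
    logistic_x0_deg: float = 0.6
    logistic_k_dep: float = 0.1
    logistic_x0_dep: float = 7.5
    move_peak: float = 0.85
    move_mu: float | None = None
    move_sigma: float | None = None
    move_mu_scale: float = 0.0
    move_sigma_scale: float = 0.02
    pull_bias: float = 0.51
    steric_block_threshold: int = 10
    move_retries: int = 5
    max_realign_angle: float = math.pi / 4
    close_radius: float = 13.5
    max_step: float = 9.0
    realign_tries: int = 40
    deposit_tries: int = 40

    def __post_init__(self) -> None:
        if not (0.0 <= self.move_peak <= 1.0):
            raise ValueError("move_peak must be a probability")
        if not (0.5 < self.pull_bias <= 1.0):
            raise ValueError(
                "pull_bias must exceed 0.5: fibers are more likely pulled than degraded"
            )
        if self.close_radius <= 0 or self.max_step <= 0:
            raise ValueError("close_radius and max_step must be positive")
        if self.steric_block_threshold < 0 or self.move_retries < 1:
            raise ValueError("invalid steric/retry configuration")

    def motility_mu(self, phenotype: Phenotype) -> float:
        if self.move_mu is not None:
            return self.move_mu
        return self.move_mu_scale * phenotype.motility_threshold

    def motility_sigma(self, phenotype: Phenotype) -> float:
        if self.move_sigma is not None:
            return self.move_sigma
        return self.move_sigma_scale * phenotype.motility_threshold

    def to_dict(self) -> dict:
        return asdict(self)

    def with_overrides(self, **kwargs) -> "ProbabilityModel":
        return replace(self, **kwargs)
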