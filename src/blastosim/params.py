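"""Model parameters, stage schedule, and rule configuration.

All numeric constants of the interaction model live in :class:`ModelParams`;
the developmental timetable in :class:`StageSchedule`; perturbation switches
(rule deletions, FGF modulation, variants) in :class:`RuleConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from .state import T_E30

__all__ = ["ModelParams", "StageSchedule", "RuleConfig", "STAGE_UNIT_DEFAULT"]

#: Duration of one stage unit (the simulated E3.0 -> E3.5 interval), on the
#: exponential-growth clock where every circle divides at rate 1.  Calibrated
#: once so that the unperturbed ensemble reaches ~132 biological cells at the
#: E4.5 endpoint, three stage units after E3.0 (ln(132/16)/3 plus a small
#: finite-population correction).
STAGE_UNIT_DEFAULT = 0.715


@dataclass
class ModelParams:
    """Numeric constants of the interaction potential and integrator.

    Distances are in cell radii (cells are unit circles/spheres); time is in
    units of the single-circle division rate.
    """

    # attraction factors of the pair potential V(d) = exp(-d) - S exp(-d/beta)
    S_default: float = 0.6          # all apolar pairs before differential adhesion
    S_pre: float = 0.4              # any pair involving a PrE cell, once Rule 3 is on
    S_neutral_adhesion: float = 0.5  # DeltaRule-3: uniform ICM attraction
    beta: float = 5.0               # attraction range
    polar_prefactor: float = 1.4    # TE-TE polarity-dependent attraction scale

    # interaction ranges (cell radii)
    global_cutoff: float = 5.0      # V = 0 beyond this for all apolar pairs
    te_te_cutoff: float = 2.5       # TE circles only feel TE circles closer than this
    te_icm_cutoff: float = 5.0
    # Range rule for ICM-ICM pairs once lineages exist: "global" = no cutoff
    # (ICM cells reach all other ICM cells by protrusions), "cutoff" = the
    # 5-radius truncation, "nearest" = true nearest neighbors only.
    icm_interaction: str = "global"
    # Interaction range of the pre-polarity morula: "cutoff" (all pairs
    # within 5 radii; the long-range attraction compacts the morula into a
    # round, tightly packed disc) or "nearest" (true nearest neighbors only,
    # minimal-overlap packing).
    morula_interaction: str = "cutoff"
    # Surface-cell criterion for Rule 1: "neighbors" (fewer than 5 nearest
    # neighbors) or "exposure" (a contact-free angular sector wider than
    # ``rule1_exposure_angle``, i.e. an apical surface).
    rule1_surface: str = "neighbors"
    rule1_exposure_angle: float = math.pi / 2
    # Neighborhood used by Rules 1, 2 and 4: the halfway-point true
    # nearest-neighbor graph ("nearest", density-adaptive) or a fixed
    # distance threshold ("radius", using ``neighbor_radius``).
    rule_neighbors: str = "nearest"
    neighbor_radius: float = 3.5    # threshold for "radius" mode graphs
    # Whether the force includes the gradient of the polar factor S through
    # the separation direction (the exact gradient of V) or treats S as a
    # quasi-static coefficient (purely central TE-TE forces).
    polar_tangential_force: bool = True
    # Interactions are restricted to true nearest neighbors (halfway-point
    # filter) for every pair involving a TE cell and for the whole
    # pre-polarity morula: without the filter the summed long-range
    # attraction compresses cells far beyond contact, the morula packs at
    # ~1.4 radii instead of "minimal overlap", and the TE shell is crushed
    # onto the ICM so that no cavity can form.
    nearest_neighbor_interactions: bool = True
    # Whether the nearest-neighbor filter also applies to TE-ICM pairs
    # (True) or only to TE-TE pairs, leaving TE-ICM at the plain 5-radius
    # range (False).
    te_icm_filtered: bool = True
    te_adj_rebuild_steps: int = 20  # filter refresh interval during relaxation

    # integrator
    dt: float = 0.1
    relax_steps: int = 200          # cap on relaxation steps per event
    relax_tol: float = 1e-3         # stop when max |dt * F| drops below this
    noise_sd_position: float = 1e-3  # additive Gaussian sd per coordinate per step
    noise_sd_angle: float = math.pi * 1e-3
    polarity_mobility: float = 0.1  # prefactor slowing polarity relative to positions

    # lifecycle
    te_division_rate_multiplier: float = 2.0  # realized by the 2-circle TE body
    apoptosis_nonpre_neighbor_threshold: int = 3  # "> 3 non-PrE neighbors" die
    fgf_undetermined_weight: float = 1.0  # 0.5 in the half-FGF4 variant
    epi_apoptosis_fraction: float = 0.0   # 0.2 in the EPI-apoptosis variant

    # schedule calibration
    stage_unit: float = STAGE_UNIT_DEFAULT

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("S_default", "S_pre", "S_neutral_adhesion"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.beta <= 1.0:
            raise ValueError("beta must exceed 1")
        for name in ("global_cutoff", "te_te_cutoff", "te_icm_cutoff"):
            if getattr(self, name) < 2.0:
                raise ValueError(f"{name} must be >= 2 cell radii")
        if self.dt <= 0 or self.relax_steps <= 0:
            raise ValueError("dt and relax_steps must be positive")
        if self.icm_interaction not in ("global", "cutoff", "nearest"):
            raise ValueError(f"unknown icm_interaction {self.icm_interaction!r}")
        if self.rule_neighbors not in ("nearest", "radius"):
            raise ValueError(f"unknown rule_neighbors {self.rule_neighbors!r}")
        if self.morula_interaction not in ("nearest", "cutoff"):
            raise ValueError(
                f"unknown morula_interaction {self.morula_interaction!r}")
        if self.rule1_surface not in ("neighbors", "exposure"):
            raise ValueError(f"unknown rule1_surface {self.rule1_surface!r}")

    @property
    def icm_global_potential(self) -> bool:
        return self.icm_interaction == "global"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StageSchedule:
    """Timetable of the four rules on the absolute simulation clock.

    Rule 1 (polarity) is triggered by cell count: it fires the first time the
    biological count reaches ``rule1_cell_count`` (the 16-cell stage; for
    wild-type growth this moment is exactly ``t_e30``).  Rules 2-4 run at
    absolute times counted from fertilization, which is what lets halved or
    aggregated embryos scale: FGF competence (Rule 2) opens at E3.0
    regardless of manipulation, differential adhesion (Rule 3) at E3.5, and
    apoptosis plus endpoint classification (Rule 4) at E4.5.
    """

    stage_unit: float = STAGE_UNIT_DEFAULT
    rule1_cell_count: int = 16
    t_e30: float = T_E30
    fgf_delay: float = 0.0  # offset added to the Rule-2 start (one unit ~ 24 h Meki)

    @property
    def rule2_start(self) -> float:
        return self.t_e30 + self.fgf_delay

    @property
    def rule2_end(self) -> float:
        """End of FGF/ERK competence (E4.0).

        Fixed in absolute time from fertilization - the window does not
        stretch when its start is delayed, and fates are inherited, not
        re-drawn, at divisions after it closes.
        """
        return self.t_e30 + 2.0 * self.stage_unit

    @property
    def t_e35(self) -> float:
        return self.t_e30 + self.stage_unit

    @property
    def t_e45(self) -> float:
        return self.t_e30 + 3.0 * self.stage_unit

    def validate(self) -> None:
        if not self.t_e30 <= self.rule2_start:
            raise ValueError("Rule 2 cannot start before E3.0")
        if not self.rule2_start <= self.t_e45:
            raise ValueError("Rule 2 must start within the competence window")


@dataclass
class RuleConfig:
    """Perturbation switches for the four rules and published variants."""

    rule1_enabled: bool = True
    rule2_mode: str = "normal"   # normal | no_fgf | excess_fgf | delayed | off
    rule3_mode: str = "normal"   # normal | neutralized
    rule4_enabled: bool = True
    fgf_undetermined_weight: float = 1.0
    epi_apoptosis_fraction: float = 0.0

    _RULE2_MODES = ("normal", "no_fgf", "excess_fgf", "delayed", "off")
    _RULE3_MODES = ("normal", "neutralized")

    def __post_init__(self) -> None:
        if self.rule2_mode not in self._RULE2_MODES:
            raise ValueError(f"unknown rule2_mode {self.rule2_mode!r}")
        if self.rule3_mode not in self._RULE3_MODES:
            raise ValueError(f"unknown rule3_mode {self.rule3_mode!r}")

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if not k.startswith("_")}
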