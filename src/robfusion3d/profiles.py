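"""Cell-type contact profiles and foci-simulation parameter sets.

Three packaged profiles emulate the study's cell types:

* ``fibroblast`` — strong distance decay, crisp compartment plaid and TADs,
  moderate trans background.
* ``PD`` (pachytene/diplotene primary spermatocytes) — shallow decay, weak
  plaid (compartments fade in meiotic prophase), elevated genome-wide trans
  contact (``meiotic_trans_boost``).
* ``RS`` (round spermatids) — steep decay, restored plaid, chromocenter
  centromere-centromere trans mass, and the fused-arm pericentromeric trans
  component whose weight is scaled by fusion penetrance.

Weights are relative mixture masses (cis mass is fixed at 1.0); they are
package defaults chosen to reproduce the qualitative regimes of the study's
cell types, not measured quantities, except ``fused_arm_weight`` in the RS
profile which is fixed by a one-time calibration (see
``scripts/calibrate_fused_arm_weight.py``) so that a fully penetrant fusion
yields a fused-pair interaction ratio of 2.0 — the homozygous value — on
ICE-normalized 500-kbp maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "CellTypeProfile",
    "FociSimParams",
    "ArmParams",
    "default_profile",
    "default_foci_params",
    "CALIBRATED_RS_FUSED_ARM_WEIGHT",
]

# One-time calibration output (scripts/calibrate_fused_arm_weight.py):
# penetrance-1.0 RS simulations on the mouse-like genome (500-kbp bins,
# 1e6 pairs, masked raw counts) give mean interaction ratio 2.0 with this
# weight; the fused-pair excess is linear in penetrance, so heterozygous
# (0.5) maps land at ~1.5.
CALIBRATED_RS_FUSED_ARM_WEIGHT = 6.80e-4


@dataclass(frozen=True)
class CellTypeProfile:
    """Relative mixture weights of the contact-pair generator for one cell type."""

    name: str
    decay_exponent: float  # cis separation density ~ s^(-decay_exponent)
    trans_background: float  # weight of uniform heterologous contacts
    compartment_strength: float  # plaid amplitude in [0, 1)
    tad_strength: float  # within-domain cis enrichment
    chromocenter_weight: float = 0.0  # centromere-centromere trans mass (RS)
    meiotic_trans_boost: float = 1.0  # multiplies trans_background (PD)
    fused_arm_weight: float = 0.0  # per-fusion pericentromeric trans mass
    loop_weight: float = 0.0  # corner-peak mass at TAD boundary pairs
    pericentromere_bp: float = 3.5e6  # proximal window used for generation

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        for attr in (
            "trans_background",
            "compartment_strength",
            "tad_strength",
            "chromocenter_weight",
            "meiotic_trans_boost",
            "fused_arm_weight",
            "loop_weight",
        ):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")

    @property
    def effective_trans(self) -> float:
        return self.trans_background * self.meiotic_trans_boost


_PROFILES = {
    "fibroblast": CellTypeProfile(
        name="fibroblast",
        decay_exponent=1.0,
        trans_background=0.15,
        compartment_strength=0.8,
        tad_strength=1.5,
        loop_weight=0.02,
    ),
    "PD": CellTypeProfile(
        name="PD",
        decay_exponent=0.7,
        trans_background=0.15,
        meiotic_trans_boost=2.0,
        compartment_strength=0.1,
        tad_strength=0.4,
    ),
    "RS": CellTypeProfile(
        name="RS",
        decay_exponent=1.3,
        trans_background=0.10,
        compartment_strength=0.6,
        tad_strength=1.0,
        chromocenter_weight=0.03,
        loop_weight=0.01,
        # fused_arm_weight filled in by default_profile from the calibration
    ),
}


def default_profile(name: str, **overrides) -> CellTypeProfile:
    """Packaged profile for ``fibroblast``, ``PD`` or ``RS`` (fields overridable)."""
    try:
        prof = _PROFILES[name]
    except KeyError:
        raise ValueError(f"unknown cell type {name!r}; expected fibroblast|PD|RS")
    # the fused-arm mass is calibrated on RS maps (where zygosity is read) and
    # reused for the other cell types, where fusions are equally visible
    if "fused_arm_weight" not in overrides:
        overrides = {**overrides, "fused_arm_weight": CALIBRATED_RS_FUSED_ARM_WEIGHT}
    return replace(prof, **overrides)


@dataclass(frozen=True)
class ArmParams:
    """Per-arm-type generative parameters for spermatocyte foci tables."""

    co_count_probs: dict[int, float]
    #: (alpha, beta) of the Beta density (on relative position / 100) for the
    #: single-CO case and for the proximal/distal foci of the two-CO case.
    pos_one_co: tuple[float, float] = (2.5, 1.3)
    pos_two_co: tuple[tuple[float, float], tuple[float, float]] = ((2.0, 5.0), (8.0, 1.5))
    axis_length_mean_um: float = 7.5
    axis_length_sd_um: float = 1.2
    double_centromere_prob: float = 0.0  # MetHom only
    synapsis_probs: dict[str, float] | None = None  # MetHet only
    #: distal displacement (added Beta mean shift) applied to 2-CEN arms
    two_cen_distal_shift_pct: float = 15.0

    def __post_init__(self) -> None:
        total = sum(self.co_count_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"co_count_probs sum to {total}, expected 1")
        if any(p < 0 or p > 1 for p in self.co_count_probs.values()):
            raise ValueError("co_count_probs must lie in [0, 1]")
        if self.synapsis_probs is not None:
            s = sum(self.synapsis_probs.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"synapsis_probs sum to {s}, expected 1")
        if self.axis_length_sd_um < 0:
            raise ValueError("axis SD must be >= 0")


@dataclass(frozen=True)
class FociSimParams:
    """Full parameter set of the foci simulator: one ArmParams per arm type."""

    arms: dict[str, ArmParams]
    rad51_per_co: float = 10.0  # mean DSB-to-CO multiplier
    synapsis_boundary_mean_pct: float = 40.0  # asynapsed arms: mean synapsis front
    synapsis_boundary_sd_pct: float = 5.0
    seed: int = 0


def default_foci_params(seed: int = 0) -> FociSimParams:
    """Packaged defaults emulating the five chromosome-arm categories.

    CO-count categoricals reflect the near-obligate single crossover per arm
    with reduced counts on homozygous metacentrics; axis lengths encode the
    observed ordering MetHet > Acr > MetHom.
    """
    arms = {
        "AcrBL6": ArmParams(
            co_count_probs={0: 0.01, 1: 0.78, 2: 0.20, 3: 0.01},
            axis_length_mean_um=7.5,
        ),
        "AcrSt": ArmParams(
            co_count_probs={0: 0.02, 1: 0.79, 2: 0.18, 3: 0.01},
            axis_length_mean_um=7.5,
        ),
        "AcrRb": ArmParams(
            co_count_probs={0: 0.03, 1: 0.81, 2: 0.15, 3: 0.01},
            axis_length_mean_um=7.0,
        ),
        "MetHet": ArmParams(
            co_count_probs={0: 0.04, 1: 0.77, 2: 0.17, 3: 0.02},
            axis_length_mean_um=8.5,
            axis_length_sd_um=1.5,
            synapsis_probs={"synapsed": 0.60, "open": 0.25, "asynapsed": 0.15},
        ),
        "MetHom": ArmParams(
            co_count_probs={0: 0.0745, 1: 0.8557, 2: 0.0698},
            axis_length_mean_um=6.5,
            double_centromere_prob=0.20,
        ),
    }
    return FociSimParams(arms=arms, seed=seed)
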