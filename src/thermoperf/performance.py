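"""Chase swim speed, exhaustive exercise effort and enzyme activity.

* ``Uchase`` — swimming speed during an exhaustive annular (circular
  raceway) chase: laps x circumference / chase duration, standardised
  to body lengths per second.
* Exhaustive exercise effort — mean chase duration x mean Uchase, in
  body lengths swum to exhaustion.  It is defined at the
  temperature-by-treatment group-mean level because chase duration and
  Uchase come from different experiments (different fish), so
  individual effort values do not exist; a per-individual variant is
  exposed but non-canonical.
* Enzyme activity — spectrophotometric rates from plate-reader
  absorbance slopes via Beer-Lambert, in nmol min^-1 mg^-1 protein and
  umol min^-1 g^-1 wet tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

#: Circumference (cm) of the annular raceway swimming zone.
DEFAULT_RACEWAY_CIRCUMFERENCE_CM = 176.0

#: Millimolar extinction coefficients, (mmol L^-1)^-1 cm^-1: NADH/NADPH
#: at 340 nm, the DTNB/thio-nitrobenzoate product at 412 nm.
EXTINCTION_MM = {340: 6.22, 412: 13.6}


class PerformanceError(ValueError):
    """Raised when a swim trial or assay record fails validation."""


@dataclass(frozen=True)
class SwimTrial:
    """One annular chase trial (fractional laps allowed)."""

    fish_id: str
    laps: float
    chase_duration: float  # s
    body_length: float  # cm
    raceway_circumference: float = DEFAULT_RACEWAY_CIRCUMFERENCE_CM

    def __post_init__(self) -> None:
        if self.laps < 0:
            raise PerformanceError("laps must be >= 0")
        if self.chase_duration <= 0:
            raise PerformanceError("chase_duration must be > 0")
        if self.body_length <= 0:
            raise PerformanceError("body_length must be > 0")
        if self.raceway_circumference <= 0:
            raise PerformanceError("raceway_circumference must be > 0")


@dataclass(frozen=True)
class EnzymeAssaySpec:
    """Plate-reader assay geometry and normalisation constants.

    ``extinction_mM`` in (mmol L^-1)^-1 cm^-1, ``pathlength`` in cm
    (computed by the operator for the final well volume),
    ``well_volume`` in uL, ``protein_per_well`` in mg,
    ``tissue_per_well`` in mg wet weight.
    """

    enzyme: str
    extinction_mM: float
    pathlength: float
    well_volume: float = 200.0
    protein_per_well: float | None = None
    tissue_per_well: float | None = None

    def __post_init__(self) -> None:
        if self.extinction_mM <= 0:
            raise PerformanceError("extinction_mM must be > 0")
        if self.pathlength <= 0:
            raise PerformanceError("pathlength must be > 0")
        if self.well_volume <= 0:
            raise PerformanceError("well_volume must be > 0")


def compute_u_chase(trial: SwimTrial) -> tuple[float, float]:
    """Chase swim speed as (BL s^-1, cm s^-1)."""
    cms = trial.laps * trial.raceway_circumference / trial.chase_duration
    return cms / trial.body_length, cms


def compute_effort(
    mean_chase_duration: float, mean_u_chase: float
) -> float:
    """Exhaustive exercise effort (BL swum) from group means.

    ``mean_chase_duration`` (s) and ``mean_u_chase`` (BL s^-1) are the
    means at one temperature-by-treatment group.
    """
    if mean_chase_duration < 0 or mean_u_chase < 0:
        raise PerformanceError("effort factors must be >= 0")
    return mean_chase_duration * mean_u_chase


def compute_individual_effort(chase_duration: float, u_chase: float) -> float:
    """Non-canonical per-individual effort (BL).

    Only meaningful when duration and speed were measured on the same
    fish, which the reference chase protocol does not provide.
    """
    return compute_effort(chase_duration, u_chase)


def compute_enzyme_activity(
    delta_a_per_min: float,
    control_delta_a: float,
    spec: EnzymeAssaySpec,
) -> dict[str, float]:
    """Enzyme activity from absorbance slopes (duplicates pre-averaged).

    net rate = (mean dA/min - control dA/min); Beer-Lambert gives the
    concentration rate net / (extinction * pathlength) in
    mmol L^-1 min^-1; times the well volume this is nmol min^-1 per
    well, normalised by protein (nmol min^-1 mg^-1 protein) and wet
    tissue mass (umol min^-1 g^-1 ww).  A negative net rate is reported
    as 0 with a flag.
    """
    net = delta_a_per_min - control_delta_a
    flagged = net < 0
    if flagged:
        logger.warning(
            "%s: net rate %.4g below control; reported as 0",
            spec.enzyme,
            net,
        )
        net = 0.0
    conc_rate = net / (spec.extinction_mM * spec.pathlength)  # mmol/L/min
    nmol_per_min_per_well = conc_rate * spec.well_volume  # (mmol/L)*(uL)=nmol
    out: dict[str, float] = {
        "enzyme": spec.enzyme,
        "nmol_min_per_well": nmol_per_min_per_well,
        "flagged": flagged,
    }
    if spec.protein_per_well:
        out["nmol_min_mg_protein"] = (
            nmol_per_min_per_well / spec.protein_per_well
        )
    if spec.tissue_per_well:
        # nmol/min/mg ww is numerically umol/min/g ww
        out["umol_min_g_ww"] = nmol_per_min_per_well / spec.tissue_per_well
    return out
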