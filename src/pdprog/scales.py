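"""Clinical rating-scale definitions.

The default battery is the six-instrument set used for measuring motor and
cognitive progression in Parkinson's disease cohorts: three motor scales
(MDS-UPDRS part III motor examination, MDS-UPDRS part II motor experiences of
daily living, Hoehn & Yahr stage) and three cognitive measures (MoCA, semantic
fluency, MDS-UPDRS item 1.1 cognitive impairment).  Scale ranges are isolated
here so a different convention (e.g. a modified Hoehn & Yahr grid) only
touches data, not code.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from ._util import ConfigurationError


@dataclass(frozen=True)
class ScaleDefinition:
    """Metadata for one clinical rating scale.

    Parameters
    ----------
    scale_id : str
        Short identifier used in visit tables.
    domain : str
        ``"motor"`` or ``"cognitive"``.
    min, max : float or None
        Fixed range of the raw score.  ``max=None`` marks an open-ended
        scale (e.g. semantic fluency word counts), which skips the percent
        transformation.
    higher_is_worse : bool
        Direction of the raw scale (True for MDS-UPDRS; False for MoCA and
        fluency, where higher scores mean better function).
    cognitive_covariates_required : bool
        Whether education covariates enter the mixed model for this scale.
    """

    scale_id: str
    domain: str
    min: float
    max: float | None
    higher_is_worse: bool
    cognitive_covariates_required: bool = False

    def __post_init__(self) -> None:
        if self.domain not in ("motor", "cognitive"):
            raise ConfigurationError(f"unknown domain {self.domain!r} for scale {self.scale_id}")
        if self.max is not None and not self.min < self.max:
            raise ConfigurationError(f"scale {self.scale_id}: min must be < max")

    @property
    def open_ended(self) -> bool:
        return self.max is None


DEFAULT_SCALES: tuple[ScaleDefinition, ...] = (
    ScaleDefinition("updrs3", "motor", 0, 132, True),
    ScaleDefinition("updrs2", "motor", 0, 52, True),
    ScaleDefinition("hoehn_yahr", "motor", 0, 5, True),
    ScaleDefinition("moca", "cognitive", 0, 30, False, True),
    ScaleDefinition("fluency", "cognitive", 0, None, False, True),
    ScaleDefinition("updrs1_1", "cognitive", 0, 4, True, True),
)

#: scale_id of the clinician motor examination, the only instrument medication
#: (levodopa-equivalent dose) directly attenuates in the sensitivity analysis.
MOTOR_EXAM_SCALE = "updrs3"


def scales_by_id(scales=DEFAULT_SCALES) -> dict[str, ScaleDefinition]:
    return {s.scale_id: s for s in scales}


def load_scales(path) -> tuple[ScaleDefinition, ...]:
    """Read scale definitions from a YAML file (list of mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return tuple(ScaleDefinition(**entry) for entry in raw)


def dump_scales(scales, path) -> None:
    entries = [
        {
            "scale_id": s.scale_id,
            "domain": s.domain,
            "min": float(s.min),
            "max": None if s.max is None else float(s.max),
            "higher_is_worse": s.higher_is_worse,
            "cognitive_covariates_required": s.cognitive_covariates_required,
        }
        for s in scales
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh)
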