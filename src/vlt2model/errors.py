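"""Exception hierarchy for the vLT2 modeling pipeline.

Athlete-level algorithm failures (no slope-1.00 point, degenerate lactate
curve, anchor outside the stage range, ...) are raised by the low-level
operations but converted to per-athlete flags by ``assemble_metrics`` so a
cohort run never aborts on one bad curve.  Structural problems (malformed
CSV, empty sessions) always raise.
"""


class Vlt2Error(Exception):
    """Base class for all package errors."""


class SchemaError(Vlt2Error):
    """Input table is missing a required column."""


class ParseError(Vlt2Error):
    """A cell could not be parsed (carries the offending row number)."""


class IntegrityError(Vlt2Error):
    """Duplicate (athlete_id, visit_date, stage_index) or similar violation."""


class InsufficientDataError(Vlt2Error):
    """Too few points/samples for the requested computation."""


class ThresholdError(Vlt2Error):
    """Base for lactate-threshold determination failures."""


class NoFirstRiseError(ThresholdError):
    """No speed in the fit domain where the curve slope reaches the criterion
    on an ascending limb (LT1 undeterminable)."""


class DegenerateCurveError(ThresholdError):
    """Lactate curve lies on or above the LT1-peak chord throughout, so the
    maximal-deviation point is undefined."""


class MissingStageError(Vlt2Error):
    """Session lacks the stage required by the fixed-speed cost method."""


class ExtrapolationError(Vlt2Error):
    """Requested anchor speed lies outside the measured stage range."""


class ImplausibleUtilizationError(Vlt2Error):
    """Fractional utilization above the plausibility guard (measurement
    inconsistency between stage VO2 and VO2peak)."""


class PairingError(Vlt2Error):
    """Paired-sample inputs have mismatched lengths."""


class UndefinedStatisticError(Vlt2Error):
    """Statistic undefined for the input (zero variance, constant column)."""


class CollinearityError(Vlt2Error):
    """Rank-deficient regression design; names the aliased columns."""


class GeneratorError(Vlt2Error):
    """Synthetic cohort generator could not produce an admissible athlete."""


class ConfigError(Vlt2Error):
    """Invalid configuration value (unknown policy, bad enum, ...)."""
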