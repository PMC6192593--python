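"""Exception hierarchy for the roost-count pipeline."""


class RoostCountError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RoostCountError):
    """Input file does not conform to the expected tabular layout."""


class DuplicationError(FormatError):
    """More than one record for the same roost x year x month."""


class InvariantError(RoostCountError):
    """A record violates the flock-size stratification identities."""


class CoverageError(RoostCountError):
    """A calendar month has no observations, so a seasonal quantity is undefined."""


class DesignError(RoostCountError):
    """A linear-model design matrix is rank deficient or otherwise unusable."""


class DenominatorUnavailableError(RoostCountError):
    """No June-July counts exist for a roost-year, so annual percentages are undefined."""


class DegenerateProfileError(RoostCountError):
    """A seasonal component is constant and cannot be range standardized."""
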