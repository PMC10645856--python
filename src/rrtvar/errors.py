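"""Exception hierarchy for rrtvar."""


class RRTVarError(Exception):
    """Base class for all rrtvar errors."""


class InvalidParameterError(RRTVarError, ValueError):
    """A model, design, or estimator parameter is outside its valid range."""


class InvalidInputError(RRTVarError, ValueError):
    """Input data violate a precondition (wrong length, too short, ...)."""


class DegeneratePopulationError(RRTVarError, ValueError):
    """A population has zero variance on a marginal needed by the method."""


class DegenerateSampleError(RRTVarError, ValueError):
    """A sample statistic needed in a denominator is zero (or the
    denominator of a ratio adjustment vanished)."""


class CollinearAuxiliaryError(RRTVarError, ValueError):
    """The two auxiliary variables are (numerically) collinear, so the
    optimum-constant system is singular."""


class IncompleteResultsError(RRTVarError, ValueError):
    """A results table is missing grid cells required by the layout."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing grid cells: {self.missing}")
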