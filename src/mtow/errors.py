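"""Exception types shared across the package."""


class MtowError(Exception):
    """Base class for package-specific errors."""


class ModelFormatError(MtowError):
    """A model file could not be parsed under the requested format."""


class ModelValidationError(MtowError):
    """A model violates a structural invariant (e.g. dangling metabolite)."""


class ConcentrationLookupError(MtowError, KeyError):
    """A stoichiometric participant has no concentration entry."""


class ThermodynamicInfeasibleError(MtowError):
    """Driving force is non-positive where the model requires forward flux."""


class EstimationError(MtowError):
    """A Gibbs-energy estimate was requested for an undetermined reaction."""


class SolverError(MtowError):
    """An optimisation backend failed to return a usable solution."""


class GridTooLargeError(MtowError):
    """Brute-force grid would exceed the allowed number of points."""
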