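"""Exception hierarchy for bsnkit.

All parameter-domain problems raise subclasses of :class:`BSNError` so callers
can distinguish modelling errors from programming errors.
"""


class BSNError(Exception):
    """Base class for all bsnkit modelling errors."""


class DomainError(BSNError, ValueError):
    """A parameter is outside its mathematical domain (e.g. non-positive flow)."""


class InfeasibleGeometryError(BSNError, ValueError):
    """Collector length meets or exceeds the circulation path length.

    The pass probability w/L would be >= 1, which the collision model cannot
    represent (the geometric picture of a short window on a long loop breaks).
    """


class UnsupportedModeError(BSNError, ValueError):
    """Operation not defined for this parameterization (e.g. closed-form
    expectation requested for flow/radius bounds, which have no elementary
    mean velocity)."""


class SearchBoundError(BSNError, RuntimeError):
    """An integer search hit its cap before closing the feasible interval."""


class InfeasibleSiteError(BSNError, ValueError):
    """A multi-site design cannot satisfy the readout requirement at one site."""

    def __init__(self, site: str, message: str | None = None):
        self.site = site
        super().__init__(message or f"site {site!r} cannot meet its readout requirement")


class ScenarioFormatError(BSNError, ValueError):
    """A scenario config file is missing fields or violates an invariant."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid scenario config: " + "; ".join(self.problems))
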