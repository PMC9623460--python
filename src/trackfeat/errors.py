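"""Exception hierarchy shared across the package."""


class TrackfeatError(Exception):
    """Base class for all package-specific errors."""


class MalformedTrackError(TrackfeatError):
    """A track violates a structural invariant (e.g. an interval with end < start)."""


class InputFormatError(TrackfeatError):
    """Raw input could not be parsed (bad date, missing column, unknown vocabulary)."""


class ConfigurationError(TrackfeatError):
    """A feature definition or operation parameter set is invalid or unresolvable."""


class MissingMilestoneError(TrackfeatError):
    """No candidate milestone event was found for a unit and the rule demands one."""
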