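"""Exception hierarchy shared across the package."""


class KissevoError(Exception):
    """Base class for all package-specific errors."""


class MalformedIntervalError(KissevoError):
    """A genomic interval is empty or inverted after coordinate conversion."""


class UnknownAnchorError(KissevoError, KeyError):
    """A neighborhood anchor could not be resolved in the annotation."""


class ConfigurationError(KissevoError):
    """Invalid or incomplete configuration (e.g. empty reference set)."""


class InconsistentOriginError(KissevoError):
    """A gene lineage is observed outside the subtree of its stated origin."""


class NoObservationError(KissevoError):
    """A gene lineage is absent from every leaf; no loss scenario is computable."""


class FixtureError(KissevoError, KeyError):
    """Unknown fixture name or fixture checksum mismatch."""


class CapacityError(KissevoError):
    """A synthetic background sequence is too short for the requested plants."""


class PipelineError(KissevoError):
    """A pipeline stage failed; the message names the stage."""
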