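"""Exception hierarchy.

Every error the package raises deliberately derives from
:class:`ReplicaMapError`, so callers can catch the package's failures
without masking programming errors.
"""


class ReplicaMapError(Exception):
    """Base class for all errors raised by replicamap."""


class ValidationError(ReplicaMapError):
    """A container violates one of its structural invariants."""


class FormatError(ReplicaMapError):
    """An on-disk artefact is missing, corrupt, or of an incompatible version."""


class ParameterError(ReplicaMapError):
    """An operation was called with an out-of-range or inconsistent parameter."""


class ChannelResolutionError(ReplicaMapError):
    """A requested m/z cannot be matched to any feature on the axis."""


class EmptyFeatureError(ReplicaMapError):
    """Peak picking produced no features above threshold."""


class EmptyBackgroundError(ReplicaMapError):
    """Background correction found no background pixels; review segmentation."""


class SpecError(ReplicaMapError):
    """A synthetic-data specification is internally inconsistent."""
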