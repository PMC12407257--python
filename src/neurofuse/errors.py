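"""Exception hierarchy.

All package errors derive from :class:`NeuroFuseError` so callers can catch
one base class; subclasses map onto the distinct failure modes the public
operations document (format/schema problems, alignment problems, invalid
parameters, degenerate numerical situations, workflow rule violations).
"""


class NeuroFuseError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(NeuroFuseError):
    """A file could not be parsed as the requested format."""


class SchemaError(NeuroFuseError):
    """Structured input (sidecar, descriptor, workflow JSON) violates its schema."""


class MetadataError(NeuroFuseError):
    """Required metadata (subject, task, ...) is missing."""


class AlignmentError(NeuroFuseError):
    """Signals cannot be aligned (missing marker, zero overlap, rate mismatch)."""


class ParameterError(NeuroFuseError, ValueError):
    """An argument is outside its documented domain."""


class InputError(NeuroFuseError, ValueError):
    """Input data violates a precondition (empty, nonpositive, wrong shape)."""


class NumericalError(NeuroFuseError):
    """A numerical procedure failed or is undefined on this input."""


class DetectionError(NeuroFuseError):
    """An event detector found nothing usable (e.g. zero R peaks)."""


class CorrectionError(NeuroFuseError):
    """An artifact-correction step cannot proceed (e.g. whole signal flagged)."""


class DescriptorError(NeuroFuseError):
    """An external-model descriptor is incomplete; ``missing`` lists every item."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__("descriptor missing: " + ", ".join(self.missing))


class WorkflowError(NeuroFuseError):
    """A workflow graph violates a structural or connection rule."""
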