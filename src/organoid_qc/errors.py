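"""Exception hierarchy for organoid-qc."""


class OrganoidQCError(Exception):
    """Base class for all organoid-qc errors."""


class ConfigurationError(OrganoidQCError):
    """Invalid configuration value (non-positive count, probability out of range, ...)."""


class SegmentationError(OrganoidQCError):
    """Segmentation produced no usable foreground."""


class MeasurementError(OrganoidQCError):
    """A measurement is undefined on the given input (empty mask, empty background, ...)."""


class RenderError(OrganoidQCError):
    """A synthetic organoid cannot be rendered on the requested canvas."""


class DomainError(OrganoidQCError):
    """An argument is outside the mathematical domain of the operation."""
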