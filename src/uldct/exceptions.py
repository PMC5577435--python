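"""Exception hierarchy for the uldct package."""


class UldctError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(UldctError, ValueError):
    """An input violates a documented precondition (shape, range, finiteness)."""


class CapacityError(UldctError, ValueError):
    """A sampling request exceeds the number of eligible positions."""


class SegmentationError(UldctError, RuntimeError):
    """Lung segmentation found no plausible lung component."""


class TrainingError(UldctError, RuntimeError):
    """Optimization diverged to a non-finite loss."""
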