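"""Exception hierarchy shared across the pipeline."""


class CanopyWiltError(Exception):
    """Base class for all package errors."""


class ImageFormatError(CanopyWiltError):
    """Input image is not decodable 8/16-bit RGB."""


class DegenerateImageError(CanopyWiltError):
    """No included pixels remain; index extraction is undefined."""


class LayoutError(CanopyWiltError):
    """A grid rectangle falls outside the mosaic bounds."""


class GenerationError(CanopyWiltError):
    """Synthetic rendering could not satisfy its target."""


class InputError(CanopyWiltError):
    """A required index value is missing or non-finite."""


class FitError(CanopyWiltError):
    """Maximum-likelihood fit failed (non-convergence or separation)."""


class EvaluationError(CanopyWiltError):
    """An accuracy or concordance statistic is undefined on the input."""
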