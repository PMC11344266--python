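"""Exception hierarchy for the dwifov package."""


class DwifovError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DwifovError, ValueError):
    """Malformed or inconsistent input files (NIfTI / bval / bvec)."""


class GeometryError(DwifovError, ValueError):
    """Invalid spatial geometry (non-invertible affine, bad voxel size)."""


class MaskingError(DwifovError, ValueError):
    """Brain-mask estimation failed (e.g. featureless input)."""


class ConfigurationError(DwifovError, ValueError):
    """Inconsistent run configuration (e.g. incomplete model bundle)."""


class TrainingDiverged(DwifovError, RuntimeError):
    """Non-finite loss encountered during optimization."""
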