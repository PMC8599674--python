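"""Exception hierarchy for morphnet."""


class MorphnetError(Exception):
    """Base class for all morphnet errors."""


class GridMismatchError(MorphnetError):
    """Two volumes (or density supports) do not share a common grid."""


class DegenerateROIError(MorphnetError):
    """An ROI has too few usable voxels for the requested operation."""


class ConfigError(MorphnetError):
    """Invalid or inconsistent configuration."""


class ZeroVarianceError(MorphnetError):
    """A statistical test received data with no variance."""
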