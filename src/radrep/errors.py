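class RadrepError(Exception):
    """Base class for all radrep errors."""


class FormatError(RadrepError):
    """Image/mask pair is malformed or inconsistent (grid or spacing mismatch)."""


class EmptyRoiError(RadrepError):
    """A mask contains no foreground voxels (natively or after resampling)."""


class SizingError(RadrepError):
    """A requested nodule does not fit in the requested grid with margin."""


class ConfigError(RadrepError):
    """A cohort or run configuration is degenerate or inconsistent."""
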