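"""Exception hierarchy.

The CLI maps these onto exit codes: config problems exit 2, data/format
problems exit 1.
"""


class HemoforceError(Exception):
    """Base class for all package errors."""


class ConfigError(HemoforceError):
    """Invalid or incomplete configuration (missing VENC, unknown keys...)."""


class FormatError(HemoforceError):
    """On-disk data violates the expected layout (grid mismatch...)."""


class DataError(HemoforceError):
    """Data is readable but unusable (empty mask, too few samples...)."""


class GeometryError(HemoforceError):
    """Degenerate geometry (parallel axis vectors, disjoint fields of view)."""


class PreprocessingError(HemoforceError):
    """Correction cannot proceed (no static tissue, rank-deficient fit)."""


class DegenerateDataError(DataError):
    """A statistical test cannot be formed (zero variance, no nonzero pairs)."""
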