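"""Exception hierarchy shared across the package.

Each public error maps to a CLI exit code (see :mod:`spherecut.cli`):
parameter errors exit 2, I/O errors 3, geometry errors 4.
"""


class SpherecutError(Exception):
    """Base class for all spherecut errors."""


class ParameterError(SpherecutError, ValueError):
    """A configuration value is out of its documented range."""


class FormatError(SpherecutError, IOError):
    """A file could not be read or written in a supported format."""


class GeometryError(SpherecutError, ValueError):
    """A spatial precondition is violated (e.g. seed outside the volume)."""


class SizeError(SpherecutError, ValueError):
    """A problem instance is too large for the requested exhaustive method."""


class ConsistencyError(SpherecutError, ValueError):
    """Two objects that must share a template/grid do not."""
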