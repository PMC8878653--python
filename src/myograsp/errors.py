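"""Exception hierarchy shared across the pipeline.

Plain ``ValueError`` is used for invalid arguments; the classes here mark
failure modes that callers may want to catch separately (a too-short
recording, a degenerate training class, a mechanism that cannot be
assembled, a malformed file, a bad configuration).
"""


class MyograspError(Exception):
    """Base class for package-specific errors."""


class WindowingError(MyograspError):
    """Recording shorter than one analysis window."""


class DegenerateClassError(MyograspError):
    """A training class has too few samples to estimate its scatter."""


class KinematicsError(MyograspError):
    """Base class for linkage-solver failures."""


class NoSolutionError(KinematicsError):
    """Newton iteration failed to converge: no assemblable pose found."""


class SingularConfigurationError(KinematicsError):
    """Loop-closure Jacobian is singular (mechanism dead point)."""


class FormatError(MyograspError):
    """Malformed data file (missing metadata, ragged rows, ...)."""


class ConfigError(MyograspError):
    """Invalid or unknown configuration key/value."""
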