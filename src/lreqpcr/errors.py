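"""Exception types raised by the analysis pipeline.

Profile-level pathologies (no amplification, aberrant kinetics, unusable
baseline range) are raised as exceptions by the low-level operations and
converted into flags by :func:`lreqpcr.windows.analyze_profile`, so a bad
well never aborts a run-level analysis.
"""


class LreError(Exception):
    """Base class for all package errors."""


class BaselineError(LreError):
    """Baseline cycle range overlaps the amplification rise."""


class NonAmplifyingError(LreError):
    """Profile never amplifies (no plateau / no half-max crossing)."""


class AberrantProfileError(LreError):
    """LRE fit is invalid (non-negative slope or non-positive intercept)."""


class WindowError(LreError):
    """No valid LRE window can be placed on the profile."""


class ProjectLoadError(LreError):
    """Project file is unreadable or structurally invalid."""


class ProjectSchemaError(ProjectLoadError):
    """Project file was written with an incompatible schema version."""


class ImportError_(LreError):
    """Profile table import failed outright (malformed layout)."""
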