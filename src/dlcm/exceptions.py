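"""Exception hierarchy for the dlcm package."""


class DLCMError(Exception):
    """Base class for all dlcm errors."""


class ConfigurationError(DLCMError):
    """Invalid user-supplied configuration (grid spec, rates, config file)."""


class AssemblyError(DLCMError):
    """Operator assembly failed (e.g. a zero-measure edge)."""


class IllegalEventError(DLCMError):
    """An event violated its precondition; signals an engine bug."""


class NoFreeBoundaryError(DLCMError):
    """The populated region covers the whole grid: the Dirichlet pressure
    problem has no boundary voxels and is singular."""


class SolverError(DLCMError):
    """A linear solve or ODE integration failed."""


class MetricsError(DLCMError):
    """Summary metrics are undefined for the given input (e.g. all-zero field)."""
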