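"""Exception hierarchy shared across omtkit modules."""


class OmtkitError(Exception):
    """Base class for all omtkit errors."""


class PDBParseError(OmtkitError):
    """A fixed-width PDB record could not be parsed; message names the line."""


class TopologyError(OmtkitError):
    """Frames of a multi-model file do not share an identical atom topology."""


class FormatOverflowError(OmtkitError):
    """A coordinate does not fit the fixed 8.3 PDB column format."""


class SelectionError(OmtkitError):
    """A selector did not resolve to the required number of atoms."""


class DegenerateGeometryError(OmtkitError):
    """A geometric primitive is undefined (zero-length arm or segment)."""


class DegenerateEmbeddingError(DegenerateGeometryError):
    """Requested internal coordinates cannot be embedded as Cartesian atoms."""


class InsufficientFramesError(OmtkitError):
    """An ensemble statistic needs more frames than were supplied."""


class UnderdeterminedError(OmtkitError):
    """Too few atom pairs for a rigid-body superposition."""


class PairingError(OmtkitError):
    """Atom selections to be paired have mismatched counts."""


class AnchorError(OmtkitError):
    """An anchor set resolved to no atoms."""


class NoInhibitionError(OmtkitError):
    """Apparent Km does not exceed Km; Ki cannot be inferred."""


class FitError(OmtkitError):
    """Nonlinear least squares failed to converge."""


class SimulationError(OmtkitError):
    """The cascade ODE integrator failed."""


class ConfigError(OmtkitError):
    """A run configuration is invalid or references missing inputs."""
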