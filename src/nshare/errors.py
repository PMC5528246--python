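"""Exception types shared across the package."""


class NshareError(Exception):
    """Base class for all package-specific errors."""


class UnknownNodeError(NshareError, KeyError):
    """A node identifier is not part of the network (identification error)."""


class PairError(NshareError, ValueError):
    """An invalid node pairing was requested (e.g. a node paired with itself)."""


class ModeError(NshareError, ValueError):
    """Operation incompatible with the network kind (directed/undirected, uni/bipartite)."""


class FormatError(NshareError, ValueError):
    """A file or table does not conform to the expected on-disk format."""


class ParameterError(NshareError, ValueError):
    """A parameter value is outside its admissible range."""


class GenerationError(NshareError, RuntimeError):
    """A synthetic-network generator could not produce a valid network."""
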