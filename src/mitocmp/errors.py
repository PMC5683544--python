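"""Exception hierarchy for mitocmp."""


class MitocmpError(Exception):
    """Base class for all package errors."""


class FormatError(MitocmpError, ValueError):
    """Malformed input file or illegal sequence characters."""


class CoordinateError(MitocmpError, ValueError):
    """A coordinate falls outside the genome after modular interpretation."""


class ParameterError(MitocmpError, ValueError):
    """A parameter violates its documented precondition."""


class PlacementError(MitocmpError, ValueError):
    """Simulated features would overlap or fall outside the sequence."""


class DecompositionError(MitocmpError, ValueError):
    """Shared gene content is insufficient to build syntenic blocks."""


class SearchSpaceError(MitocmpError, ValueError):
    """Exact rearrangement search refused: state space too large."""


class UndefinedDistanceError(MitocmpError, ValueError):
    """No comparable sites remain after gap/ambiguity exclusion."""
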