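"""Exception hierarchy shared across the package."""


class RsnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RsnetError, ValueError):
    """Malformed input table (missing columns, non-binary entries, ...)."""


class EmptyInputError(RsnetError, ValueError):
    """An input that must contain data is empty."""


class SynonymMapError(RsnetError, ValueError):
    """Chained or cyclic driver synonym map."""


class InfeasibleMarginsError(RsnetError, ValueError):
    """Requested degree sequences violate the Gale-Ryser condition."""


class UndefinedStatisticError(RsnetError, ValueError):
    """A statistic is undefined for the given input (too few nodes)."""


class MissingAttributeError(RsnetError, KeyError):
    """Nodes lack a required attribute classification."""


class StageError(RsnetError, RuntimeError):
    """A pipeline stage failed; the stage name is carried in the message."""
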