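"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`ComorbnetError`, so callers (and the CLI) can distinguish
validation problems from genuine bugs.
"""


class ComorbnetError(Exception):
    """Base class for all errors raised by comorbnet."""


class FormatError(ComorbnetError):
    """An input file violates its format contract (missing column, short line...)."""


class UnknownEntityError(ComorbnetError, KeyError):
    """A disease, gene, miRNA or set id was requested that the data does not contain."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class ConfigurationError(ComorbnetError):
    """A required auxiliary input is missing or a configuration is infeasible."""


class DomainError(ComorbnetError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class UndefinedScoreError(ComorbnetError):
    """A score is mathematically undefined for the given pair (e.g. empty term union)."""
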