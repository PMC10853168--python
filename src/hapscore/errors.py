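"""Exception hierarchy shared across the package."""


class HapsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HapsError):
    """A constant table, config file or parameter set is incomplete/invalid."""


class MissingAlleleError(HapsError, KeyError):
    """An HLA allele name could not be resolved in a sequence store."""

    def __str__(self) -> str:  # KeyError quotes its repr otherwise
        return HapsError.__str__(self)


class DataError(HapsError, ValueError):
    """Input records violate a documented invariant."""
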