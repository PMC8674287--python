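"""Exception hierarchy shared across the package."""


class FloraHomError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FloraHomError):
    """Malformed input file or record."""


class EmptyInputError(FloraHomError):
    """An operation received no usable records."""


class MissingReferenceError(FloraHomError, KeyError):
    """An identifier (region, species, tip label) is absent from a registry."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class DomainError(FloraHomError, ValueError):
    """An argument lies outside its mathematical domain."""


class UndefinedSimilarityError(DomainError):
    """Similarity is undefined (empty effective flora)."""


class FitError(FloraHomError):
    """A model fit failed or is undefined."""


class NoHalvingError(FitError):
    """Similarity does not decrease with distance, so no halving distance exists."""


class CollinearityError(FitError):
    """Design matrix is rank deficient."""
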