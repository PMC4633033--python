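"""Exception hierarchy shared across the pipeline stages."""


class BmiconnError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(BmiconnError, ValueError):
    """A synthetic-cohort specification violates its invariants."""


class InvalidArgumentError(BmiconnError, ValueError):
    """An operation received arguments outside its contract."""


class DegenerateInputError(BmiconnError, ValueError):
    """Input is formally valid but statistically degenerate (zero variance etc.)."""


class ReferentialIntegrityError(BmiconnError, KeyError):
    """A record refers to a region or subject that does not exist."""


class ParseError(BmiconnError, ValueError):
    """An on-disk file failed schema or type validation."""


class ConfigError(BmiconnError, ValueError):
    """Pipeline configuration is invalid (unknown keys, bad values, missing paths)."""
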