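"""Exception hierarchy for survey validation and scenario construction."""


class CycleshiftError(Exception):
    """Base class for all package errors."""


class SchemaError(CycleshiftError):
    """A table is missing a mandatory column or has an unparseable dtype."""


class IntegrityError(CycleshiftError):
    """Referential integrity is broken (orphan trips, duplicate ids...)."""


class ValidationError(CycleshiftError):
    """A row violates a type invariant (bad category, out-of-range value)."""


class InfeasibleConfigError(CycleshiftError):
    """A generator or scenario configuration cannot be realised."""


class CoverageError(CycleshiftError):
    """A lookup table does not cover a required stratum or distance band."""
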