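"""Exception hierarchy shared across the pipeline."""


class TilapiaGhError(Exception):
    """Base class for all package errors."""


class CoordinateError(TilapiaGhError):
    """Invalid signed CDS coordinate (e.g. position 0, reversed span)."""


class ValidationError(TilapiaGhError):
    """Malformed input value or record."""


class ConfigError(TilapiaGhError):
    """Unknown preset or incomplete scenario configuration."""


class IncompatibleGenotypeError(TilapiaGhError):
    """Observed base(s) not drawn from the two parental alleles at a site."""


class DegenerateInputError(TilapiaGhError):
    """Zero-variance or otherwise degenerate cohort where a test is undefined."""
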