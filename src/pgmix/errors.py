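"""Exception hierarchy shared across the package."""


class PgmixError(Exception):
    """Base class for all pgmix errors."""


class InputError(PgmixError, ValueError):
    """Invalid argument values (bad weights, unknown alleles, bad ranges)."""


class DataFormatError(PgmixError, ValueError):
    """Malformed input files (schema mismatch, bad rows, failed validation)."""
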