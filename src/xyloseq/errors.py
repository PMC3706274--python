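"""Exception hierarchy shared across the pipeline stages."""


class XyloseqError(Exception):
    """Base class for all package-specific errors."""


class FormatError(XyloseqError):
    """A file does not conform to its expected tabular dialect."""


class TableValueError(XyloseqError, ValueError):
    """A parsed value violates a domain invariant (e.g. negative FPKM)."""


class DesignError(XyloseqError):
    """Inputs are individually valid but mutually inconsistent
    (unknown condition label, mismatched feature universes, axis mismatch)."""


class ConfigError(XyloseqError, ValueError):
    """A configuration value is outside its admissible range."""


class InputError(XyloseqError, ValueError):
    """An operation received an input it cannot meaningfully process
    (e.g. an empty differential gene set)."""
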