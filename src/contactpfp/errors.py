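"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigurationError -> 2, InputError
(and its DegenerateInputError subclass) -> 3.
"""


class ContactPFPError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ContactPFPError):
    """A parameter or configuration value is inconsistent with the data."""


class InputError(ContactPFPError):
    """An input file or in-memory object violates its contract."""


class DegenerateInputError(InputError):
    """Structurally valid input that is too small or empty to process."""
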