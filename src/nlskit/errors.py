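"""Exception types shared across the package."""


class NlskitError(Exception):
    """Base class for package errors."""


class ValidationError(NlskitError):
    """Invalid user input or argument (CLI exit code 2)."""


class ParseError(NlskitError):
    """A structured input (PDB, motif string, config) could not be parsed."""
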