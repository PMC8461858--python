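"""Exception hierarchy.

``InputError`` covers malformed or missing inputs (CLI exit code 2),
``ComputationError`` covers failures inside the method itself (exit code 3).
"""


class MencError(Exception):
    """Base class for all package errors."""


class InputError(MencError):
    """A file could not be read or does not conform to its format contract."""


class FormatError(InputError):
    """A parseable file violates a structural invariant (non-binary cell, duplicate gene, ...)."""


class ComputationError(MencError):
    """A stage of the method received data on which its output is undefined."""
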