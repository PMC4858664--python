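"""Exception hierarchy.

The command-line layer maps these onto exit codes: input problems
(missing/malformed files, bad sequences) exit 2, configuration problems
(bad parameter values) exit 3, violated internal invariants exit 4.
"""


class AggscapeError(Exception):
    """Base class for all package errors."""


class InputError(AggscapeError):
    """A user-supplied file or value is missing or malformed."""


class ConfigError(AggscapeError):
    """A parameter value violates its contract."""


class InternalError(AggscapeError):
    """An internal invariant was violated; indicates a bug."""
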