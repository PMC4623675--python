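"""Exception hierarchy.

All pipeline errors derive from :class:`RhizographError` so callers can
catch the package's failures with one clause while still distinguishing
bad inputs from bad configuration or degenerate data.
"""


class RhizographError(Exception):
    """Base class for all package errors."""


class InputError(RhizographError, ValueError):
    """An input file or array is unreadable or structurally invalid."""


class ConfigurationError(RhizographError, ValueError):
    """Required configuration (e.g. image resolution) is missing or invalid."""


class DegenerateInputError(RhizographError, ValueError):
    """Input is valid but too sparse/degenerate for the requested operation
    (e.g. fewer background samples than surface parameters, empty skeleton)."""


class StateError(RhizographError, RuntimeError):
    """Operation called before a required earlier stage (e.g. scoring a
    graph with an unfitted thickness mixture)."""
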