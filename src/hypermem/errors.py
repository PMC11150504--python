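"""Exception hierarchy.

``InputError`` maps to exit code 2 on the command line, everything else to 1.
"""


class HypermemError(Exception):
    """Base class for all package errors."""


class InputError(HypermemError):
    """Malformed user input: files, node ids, lags, CLI arguments."""


class ConfigError(HypermemError):
    """Invalid model or fixture configuration."""
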