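"""Exception types raised across the package."""


class DivscanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DivscanError):
    """Invalid configuration or inconsistent inputs (bad sizes, unknown samples)."""


class ParseError(DivscanError):
    """Malformed input file."""


class UnknownScenarioError(ConfigurationError):
    """Scenario label outside the four supported injection labels."""
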