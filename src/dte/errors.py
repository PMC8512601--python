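"""Exception types shared across the package."""


class DTEError(Exception):
    """Base class for package-specific errors."""


class ConfigError(DTEError, ValueError):
    """Invalid or inconsistent experiment configuration (CLI exit code 2)."""


class DataError(DTEError, ValueError):
    """Data-integrity violation such as mismatched lengths or mixed channel
    counts (CLI exit code 3)."""
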