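"""Exception types shared across the pipeline."""


class ErphagyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ErphagyError):
    """A generator or pipeline configuration is invalid."""


class DesignError(ErphagyError):
    """A plex design is inconsistent with the requested analysis."""
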