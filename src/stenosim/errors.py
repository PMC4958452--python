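"""Exception types shared across the package."""


class StenosimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StenosimError):
    """A parameter set violates a physical or structural constraint."""


class OutOfLumenError(StenosimError):
    """A field evaluation point lies outside the vessel lumen."""


class SimulationError(StenosimError):
    """A numerical step failed (overflow, singular geometry, mismatch)."""
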