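"""Exception hierarchy shared across the package."""


class VavrError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(VavrError, ValueError):
    """A generator or model parameter violates its invariant."""


class InputError(VavrError, ValueError):
    """Invalid data passed to an operation (wrong range, shape, or sign)."""


class ConfigurationError(VavrError):
    """Pipeline or generator configuration is incomplete or inconsistent."""


class UndefinedMetricError(VavrError):
    """The requested metric has no defined value on this input
    (e.g. fully retrograde plane for NFD, all-zero field for WPD)."""
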