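"""Exception hierarchy for the advisory engine."""


class VentAdvisorError(Exception):
    """Base class for all package errors."""


class DomainError(VentAdvisorError, ValueError):
    """An input lies outside the documented domain of a function."""


class InfeasibleSettingsError(VentAdvisorError):
    """The requested ventilator settings cannot sustain gas exchange.

    Raised e.g. when tidal volume does not exceed serial dead space (no
    alveolar ventilation) or when no spontaneous breathing equilibrium exists.
    """


class ConvergenceError(VentAdvisorError):
    """A numerical solve failed to converge; carries diagnostics in args."""


class ConfigError(VentAdvisorError, ValueError):
    """A configuration document failed schema validation."""
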