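"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Raised when a configuration value violates a model precondition."""


class IntegrationError(RuntimeError):
    """Raised when numerical integration produces a non-finite state.

    Carries the neuron index and simulation time at which the state first
    became non-finite, so blown-up runs can be traced to a cell.
    """

    def __init__(self, message, neuron_index=None, time_ms=None):
        super().__init__(message)
        self.neuron_index = neuron_index
        self.time_ms = time_ms


class NoOscillationError(RuntimeError):
    """Sentinel error for analyses that require at least one detected cycle."""
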