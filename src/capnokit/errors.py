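"""Exception hierarchy for capnokit."""


class CapnokitError(Exception):
    """Base class for all capnokit errors."""


class ParameterError(CapnokitError, ValueError):
    """Invalid user-supplied parameter (morphology, artefact window, ...)."""


class DegenerateInputError(CapnokitError, ValueError):
    """Input too short or otherwise degenerate for the requested operation."""


class SplitError(CapnokitError, ValueError):
    """Cross-validation plan cannot be constructed (e.g. too few patients)."""


class ConfigurationError(CapnokitError, ValueError):
    """Inconsistent configuration (e.g. feature missing from the region map)."""
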