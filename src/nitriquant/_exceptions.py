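"""Exception hierarchy shared across the package."""


class NitriquantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NitriquantError):
    """Invalid parameter, threshold, preset label, or copy-model entry."""


class InputDataError(NitriquantError, ValueError):
    """Malformed or inconsistent input data (sequences, tables, records)."""


class FeatureLookupError(NitriquantError, KeyError):
    """A lineage, marker, or feature referenced but not defined."""
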