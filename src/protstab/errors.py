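"""Exception hierarchy shared across the package."""


class ProtstabError(Exception):
    """Base class for all package errors."""


class ConfigError(ProtstabError):
    """A configuration object (simulation spec, model config, CLI option)
    is internally inconsistent or out of its allowed domain."""


class InputError(ProtstabError):
    """Data supplied to an operation violates its contract
    (negative intensities, duplicate keys, unknown references, ...)."""
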