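"""Exception hierarchy shared by all pipeline stages."""


class MethArrayError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MethArrayError):
    """A file or table does not conform to the documented format."""


class IntegrityError(MethArrayError):
    """Input is well-formed but internally inconsistent (duplicate ids,
    coordinates out of range, probes missing from the manifest, ...)."""


class ConfigError(MethArrayError):
    """A simulation or pipeline configuration is invalid."""
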