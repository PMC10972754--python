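"""Exception hierarchy."""


class BaitrankError(Exception):
    """Base class for all package errors."""


class ConfigError(BaitrankError):
    """Invalid or infeasible configuration."""


class InputError(BaitrankError):
    """Malformed or inconsistent input data."""


class UnknownGeneError(InputError):
    """A gene identifier was referenced but is absent from the annotation."""


class PipelineError(BaitrankError):
    """A pipeline stage failed; the message names the stage."""
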