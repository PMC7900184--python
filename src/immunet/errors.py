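"""Exception hierarchy shared across the pipeline."""


class ImmunetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ImmunetError):
    """A user-supplied parameter or config file is invalid."""


class PipelineError(ImmunetError):
    """A pipeline stage cannot proceed with the data it was given."""
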