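"""Exception hierarchy shared across the pipeline."""


class CCCFError(Exception):
    """Base class for all package errors."""


class ParameterError(CCCFError, ValueError):
    """A simulation or configuration parameter is invalid; names the field."""


class DegenerateInputError(CCCFError, ValueError):
    """Input data violates a precondition (e.g. zero-count cells)."""


class EmptySignatureError(CCCFError, ValueError):
    """Differential expression produced an empty signature; scoring is undefined."""


class EmptyFeatureSetError(CCCFError, ValueError):
    """Feature selection produced an empty intersection."""


class OrientationError(CCCFError, ValueError):
    """Pseudotime orientation needs both high- and low-labelled cells."""


class StageOrderError(CCCFError, RuntimeError):
    """A pipeline stage ran before the stage that produces its input."""
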