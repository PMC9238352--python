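"""Exception hierarchy shared across the pipeline stages."""


class KoPathBenchError(Exception):
    """Base class for all package errors."""


class ValidationError(KoPathBenchError, ValueError):
    """A parameter or input violates a documented invariant."""


class KgmlParseError(KoPathBenchError):
    """KGML file could not be parsed into a pathway graph."""


class EmptyPathwayError(KgmlParseError):
    """KGML file contains no gene entries."""


class NoThresholdError(KoPathBenchError):
    """Change-point threshold cannot be determined from the edge scores."""


class NotComputableError(KoPathBenchError):
    """Pathway perturbation system is singular; pathway must be skipped."""


class BenchmarkError(KoPathBenchError, ValueError):
    """Knockout benchmark is degenerate (missing positives or negatives)."""
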