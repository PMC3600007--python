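"""Exception hierarchy for rarekernel."""


class RareKernelError(Exception):
    """Base class for all rarekernel errors."""


class ParseError(RareKernelError, ValueError):
    """A file could not be parsed under its named standard."""


class ValidationError(RareKernelError, ValueError):
    """Input values violate a documented contract (e.g. genotype not in {0,1,2})."""


class ShapeError(RareKernelError, ValueError):
    """Mismatched array shapes."""


class DegenerateWeightsError(RareKernelError, ValueError):
    """All variant weights are zero; a weighted kernel is undefined."""


class KernelValidityError(RareKernelError, ValueError):
    """A similarity matrix failed symmetry / positive-semi-definiteness checks."""


class DegenerateStatisticError(RareKernelError, ArithmeticError):
    """A test statistic is undefined (zero denominator / degenerate geometry)."""


class InsufficientGroupError(RareKernelError, ValueError):
    """A case or control group is too small for a pairwise statistic."""


class EmptyRegionError(RareKernelError, ValueError):
    """No variants remain after filtering."""


class SamplingLimitError(RareKernelError, RuntimeError):
    """Retrospective sampling could not reach the requested case/control counts."""
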