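"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: input/contract problems exit with 2,
capability problems (e.g. asking for gradients from a generator that cannot
provide them) exit with 3.
"""


class ConstellationError(Exception):
    """Base class for package errors."""


class ContractError(ConstellationError, ValueError):
    """An argument violates an operation's contract (dimension or shape
    mismatch, invalid configuration, mismatched stimuli...)."""


class InputError(ConstellationError, ValueError):
    """Input data is unusable (empty dataset, degenerate stimulus...)."""


class DegenerateShapeError(InputError):
    """An outline is too short to carry at least two dots per polyline."""


class CapacityError(InputError):
    """Distractor placement is impossible under the separation constraint."""


class CapabilityError(ConstellationError):
    """The requested operation needs a capability the object lacks
    (e.g. gradient search on a non-differentiable generator)."""


class UndefinedCorrelationError(ConstellationError, ValueError):
    """Too few retained cells or zero variance after zero-exclusion."""
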