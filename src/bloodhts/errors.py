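"""Exception hierarchy shared across the package.

Three broad families are distinguished so the command-line layer can map
them onto distinct exit codes: configuration problems, data problems and
numerical failures.
"""


class BloodHtsError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BloodHtsError):
    """Invalid run configuration (shares not summing to one, bad horizon...)."""


class DataError(BloodHtsError):
    """Malformed or inconsistent input data."""


class NumericalError(BloodHtsError):
    """A numerical routine failed (singular system, non-convergence...)."""


class MalformedHierarchyError(ConfigError):
    """The node tree is not a strict tree (cycle, multiple parents, no root)."""


class UnbalancedTreeError(ConfigError):
    """Bottom nodes do not all sit at the same level."""


class LabelError(DataError):
    """A node label does not match the declared hierarchy."""


class GapError(DataError):
    """Missing period/node combinations in a series file."""


class ChronologyError(DataError):
    """Holdout window does not immediately follow the training window."""


class ZeroTotalError(DataError):
    """A top-level historical value is zero, so shares are undefined."""


class ZeroActualError(DataError):
    """An actual value is zero, so a percentage error is undefined."""


class ZeroDenominatorError(NumericalError):
    """A sibling-group forecast sum is zero in the forecast-proportion scheme."""


class IncompleteForecastError(DataError):
    """A base-forecast set is missing forecasts for required nodes."""
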