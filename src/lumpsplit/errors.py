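"""Exception hierarchy for lumpsplit.

All errors derive from :class:`LumpSplitError` so callers can catch the
package's failures with one clause; each subclass names the violated
contract.
"""


class LumpSplitError(Exception):
    """Base class for all lumpsplit errors."""


class InvalidDescriptorError(LumpSplitError, ValueError):
    """A facial phenotype descriptor is malformed (zero norm, non-finite, wrong shape)."""


class MissingImageError(LumpSplitError, KeyError):
    """A referenced image id is absent from the descriptor collection."""


class EmptyCohortError(LumpSplitError, ValueError):
    """A cohort contains no images."""


class OverlappingCohortsError(LumpSplitError, ValueError):
    """Two cohorts that must be disjoint share images."""


class EmptyDatasetError(LumpSplitError, ValueError):
    """Filtering removed every syndrome from the collection."""


class InsufficientSyndromesError(LumpSplitError, ValueError):
    """Fewer syndromes than cross-validation folds."""


class EmptyDistributionError(LumpSplitError, ValueError):
    """A control distance distribution is empty."""


class UndefinedPpvError(LumpSplitError, ZeroDivisionError):
    """PPV denominator is zero (sensitivity 0 with specificity 1)."""


class DegenerateTableError(LumpSplitError, ValueError):
    """A 2x2 contingency table with no positive margin."""


class InvalidCountError(LumpSplitError, ValueError):
    """A count parameter outside its admissible range."""


class ConfigError(LumpSplitError, ValueError):
    """Invalid simulation configuration."""


class InsufficientSamplesError(LumpSplitError, ValueError):
    """Too few samples for the requested decomposition or model fit."""


class DegenerateDesignError(LumpSplitError, ValueError):
    """A model design with a group of fewer than two samples, or a single class."""


class MissingProbeError(LumpSplitError, KeyError):
    """Signature probes absent from a beta matrix."""

    def __init__(self, probe_ids):
        self.probe_ids = list(probe_ids)
        super().__init__(f"signature probes missing from matrix: {self.probe_ids}")
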