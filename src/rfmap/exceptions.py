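"""Exception hierarchy for rfmap.

All rfmap errors derive from :class:`RfmapError` so callers can catch the
package's failures with a single except clause.
"""


class RfmapError(Exception):
    """Base class for all rfmap errors."""


class InvalidConfigError(RfmapError, ValueError):
    """A configuration object violates its invariants."""


class InsufficientDataError(RfmapError, ValueError):
    """Too few observations to fit or estimate the requested quantity."""


class DegenerateFieldError(RfmapError, ValueError):
    """All field values identical; no spatial structure can be estimated."""


class NoNeighborError(RfmapError, ValueError):
    """No measurement found within the kriging search neighborhood."""


class InvalidVarianceError(RfmapError, ValueError):
    """A variance argument is negative."""


class ZeroDayError(RfmapError, ValueError):
    """A sensor day contains only zero field values and cannot be normalized."""


class DegenerateDistributionError(RfmapError, ValueError):
    """A sample vector has zero spread; distribution fitting is undefined."""


class UnderdeterminedDesignError(RfmapError, ValueError):
    """Experimental design has fewer runs than surrogate coefficients."""


class InsufficientTrainingError(RfmapError, ValueError):
    """Too few training maps for the map-surrogate decomposition."""


class InvalidUsageError(RfmapError, ValueError):
    """Mobile-usage parameters are inconsistent (e.g. data volume without throughput)."""


class AllocationError(RfmapError, ValueError):
    """Census population cannot be allocated (populated zone with no housing area)."""
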