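"""Exception hierarchy shared across the toolkit."""


class MtcbeError(Exception):
    """Base class for all toolkit errors."""


class AmbiguousSequenceError(MtcbeError, ValueError):
    """Sequence contains bases outside the A/C/G/T alphabet."""


class BoundaryError(MtcbeError, ValueError):
    """A 5' base was requested for a TALE site flush with the sequence edge.

    Raised instead of silently reporting "non-compliant": a site whose
    upstream base falls outside the supplied window has an *unknown* 5'
    base, which is a different statement than a known non-T base.
    """


class BoundsError(MtcbeError, IndexError):
    """An interval falls outside the sequence it was applied to."""


class InvalidTargetError(MtcbeError, ValueError):
    """The requested target position is not an editable cytosine (C or G)."""


class ParameterError(MtcbeError, ValueError):
    """A simulation or quantification parameter is outside its valid range."""


class BarcodeConfigError(MtcbeError, ValueError):
    """Demultiplexing barcodes violate the length/distance contract."""


class MetricsError(MtcbeError, ValueError):
    """A summary statistic is undefined for the given inputs."""


class HomologyError(MtcbeError, ValueError):
    """Two records are too diverged to pairwise-align reliably."""
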