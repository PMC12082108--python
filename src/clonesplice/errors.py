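"""Exception hierarchy.

Every contract violation raises a subclass of :class:`CloneSpliceError`;
the CLI maps these to a nonzero exit with the message on stderr.
"""


class CloneSpliceError(Exception):
    """Base class for all package errors."""


class InputError(CloneSpliceError):
    """Malformed or out-of-contract input (bad config value, malformed file row)."""


class SimulationError(CloneSpliceError):
    """Internal failure of a generator (e.g. clone fractions escaping [0,1])."""


class UnsupportedModelError(CloneSpliceError):
    """A zygosity/copy-number model outside the supported heterozygous-diploid case."""


class NonIdentifiableError(CloneSpliceError):
    """Too little data to fit (e.g. a single time point per clone)."""


class DisjointWindowsError(CloneSpliceError):
    """Two VAF series with non-overlapping observation windows."""


class UndefinedTestError(CloneSpliceError):
    """A statistical test with an empty sample (n = 0)."""


class IncompatibleMatrixError(CloneSpliceError):
    """Binary mutation matrix violates the three-gamete (perfect phylogeny) condition.

    Carries the offending variant pair in :attr:`pair`.
    """

    def __init__(self, pair, message=None):
        self.pair = tuple(pair)
        super().__init__(
            message
            or f"variants {self.pair[0]!r} and {self.pair[1]!r} violate the "
            "three-gamete condition: carrier sets overlap but are not nested"
        )
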