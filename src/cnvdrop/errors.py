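"""Exception types raised by the quantification pipeline."""


class CnvDropError(ValueError):
    """Base class for all cnvdrop-specific errors."""


class EmptyWellError(CnvDropError):
    """A well with zero accepted droplets carries no information."""


class SaturationError(CnvDropError):
    """All droplets positive: the Poisson occupancy is unbounded."""


class ReferenceFailureError(CnvDropError):
    """The reference (housekeeper) channel detected no template."""


class MissingDataError(CnvDropError):
    """A required replicate set, genotype or count table is absent."""
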