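"""Exception hierarchy for the screening pipeline.

Every error raised by the package derives from :class:`CarrierScreenError`,
so callers (and the CLI) can distinguish pipeline failures from programming
errors. Subclasses mirror the failure modes of the individual stages.
"""


class CarrierScreenError(Exception):
    """Base class for all errors raised by carrierscreen."""


class CapacityError(CarrierScreenError):
    """Strain catalog does not fit the plate interior."""


class ShapeError(CarrierScreenError):
    """A plate layout has the wrong grid dimensions."""


class GeometryError(CarrierScreenError):
    """Degenerate image geometry (zero-area windows, collapsed corners)."""


class FormatError(CarrierScreenError):
    """Unsupported image or table format."""


class LayoutError(CarrierScreenError):
    """Measurement grid does not match the plate layout."""


class PairingError(CarrierScreenError):
    """Drug and control plates share no strains."""


class DomainError(CarrierScreenError):
    """Argument outside its mathematical domain."""


class RangeError(CarrierScreenError):
    """Requested inhibition level is not bracketed by the measured data."""


class EstimationError(CarrierScreenError):
    """Too few usable samples to estimate a growth rate."""


class StagnationError(CarrierScreenError):
    """No strain grows in the simulated pool; stop biomass unreachable."""


class NormalizationError(CarrierScreenError):
    """A pool condition cannot be normalized (all-zero signal)."""


class InputError(CarrierScreenError):
    """Empty or structurally invalid input table."""


class ConfigError(CarrierScreenError):
    """Invalid or incomplete run configuration."""


class IntegrityError(CarrierScreenError):
    """Packaged fixture does not match its recorded checksum."""
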