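"""Exception hierarchy shared across the package."""


class ExomeCarrierError(Exception):
    """Base class for all package-specific errors."""


class PanelValidationError(ExomeCarrierError):
    """A mutation panel (or one of its rows) failed validation."""


class PanelParseError(PanelValidationError):
    """A panel file could not be parsed; carries row/field diagnostics."""


class AmbiguousMatchError(ExomeCarrierError):
    """More than one panel entry matched a single observed variant."""


class AlleleNormalizationError(ExomeCarrierError):
    """Allele pair inconsistent with the supplied reference context."""


class ObservationError(ExomeCarrierError):
    """A site observation violates its invariants (e.g. ac > an)."""


class ManifestError(ExomeCarrierError):
    """Sample manifest inconsistency (unknown sample, population clash)."""


class UndefinedEstimateError(ExomeCarrierError):
    """Carrier estimate requested for an observation with an == 0."""


class UnattainableTargetError(ExomeCarrierError):
    """Detection target cannot be reached (p·(1−σ) == 0)."""
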