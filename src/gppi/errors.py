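"""Exception hierarchy for gppi.

All package-specific failures derive from :class:`GppiError` so callers (and
the CLI) can distinguish usage/data problems from genuine bugs.
"""


class GppiError(Exception):
    """Base class for all gppi errors."""


class StructureFormatError(GppiError):
    """The structure document could not be parsed."""


class EmptyStructureError(GppiError):
    """No residue with a Calpha atom survived filtering."""


class AccessionError(GppiError):
    """Identifier does not look like a UniProt accession."""


class NotFoundError(GppiError):
    """Remote repository has no model for the accession."""


class OfflineError(GppiError):
    """Network fetch required but network access is disabled."""


class DegenerateScaleError(GppiError):
    """A property column is constant and cannot be min-max normalized."""


class EncodingError(GppiError):
    """A residue code is missing from the property table."""


class GraphError(GppiError):
    """Invalid contact-graph input (e.g. fewer than two residues)."""


class ConfigError(GppiError):
    """Invalid model or training configuration."""


class SplitError(GppiError):
    """No leakage-free split with a non-empty validation side exists."""


class MetricError(GppiError):
    """Metric undefined for the given inputs (e.g. single-class AUC)."""
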