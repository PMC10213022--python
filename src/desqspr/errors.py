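"""Exception hierarchy.

``DesqsprError`` is the base for everything the library raises on purpose,
so callers (and the CLI) can distinguish expected failures from bugs.
"""


class DesqsprError(Exception):
    """Base class for all desqspr errors."""


class StructureParseError(DesqsprError):
    """A SMILES string could not be parsed into a molecular graph."""


class DescriptorError(DesqsprError):
    """A descriptor is undefined or unsupported for the given input."""


class ModelLookupError(DesqsprError):
    """No registry model matches the requested id / ratio / temperature."""


class PredictionError(DesqsprError):
    """Prediction inputs violate a model precondition (e.g. P <= 0)."""


class DataValidationError(DesqsprError):
    """A data table or record violates the schema or a physical bound."""


class SupplementaryMissingError(DataValidationError):
    """The optional per-point supplementary spreadsheet is not present."""


class FitError(DesqsprError):
    """A regression cannot be carried out (rank deficiency, n too small...)."""
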