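"""Exception hierarchy shared across the toolkit."""


class TumorkitError(Exception):
    """Base class for all toolkit errors."""


class UnlabeledNameError(TumorkitError):
    """Filename does not follow the Yxx/Nxx labeling convention."""


class FormatError(TumorkitError):
    """File is unreadable, corrupt, or missing a required field."""


class ShapeError(TumorkitError):
    """Array shapes are degenerate or mutually inconsistent."""


class ArityError(TumorkitError):
    """Wrong number of inputs (e.g. fewer than four MRI modalities)."""


class SizeError(TumorkitError):
    """A collection is empty or too small for the requested operation."""


class DegenerateDataError(TumorkitError):
    """Training data cannot support learning (single class, all-empty masks)."""


class SpecError(TumorkitError):
    """Phantom specification is geometrically invalid."""
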