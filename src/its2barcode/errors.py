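"""Exception hierarchy shared across the pipeline.

Every error a caller is expected to handle derives from :class:`Its2Error`,
so the CLI can map the whole family to exit code 2.
"""


class Its2Error(Exception):
    """Base class for all its2barcode errors."""


class ValidationError(Its2Error):
    """Malformed or inconsistent input (files, sequences, structures)."""


class ConstraintError(Its2Error):
    """Folding constraints that are mutually inconsistent or infeasible."""


class UndefinedDistanceError(Its2Error):
    """A pairwise distance with zero comparable sites."""


class TemplateMismatchError(Its2Error):
    """Barcodes or structures that do not share the required template."""
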