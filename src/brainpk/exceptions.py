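"""Exception hierarchy for brainpk."""


class BrainPKError(Exception):
    """Base class for all brainpk errors."""


class InvalidInputError(BrainPKError, ValueError):
    """A value violates a computational precondition (e.g. nonpositive plasma
    concentration, unbound fraction outside [0, 1])."""


class AssayFailureError(BrainPKError):
    """An assay yielded no usable replicate/slice (all records invalid)."""


class QCFailureError(BrainPKError):
    """Every record of an assay failed quality control."""


class SchemaError(BrainPKError, ValueError):
    """A table does not conform to its declared schema (missing columns,
    wrong transition count, unparseable values)."""
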