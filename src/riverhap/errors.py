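"""Exception hierarchy shared across the pipeline."""


class RiverhapError(Exception):
    """Base class for all package errors."""


class InputError(RiverhapError):
    """Malformed or inconsistent user input (bad file, bad value)."""


class AlignmentError(InputError):
    """Sequences that do not form a valid alignment."""


class ConsistencyError(InputError):
    """Cross-file inconsistency (e.g. alignment id missing from metadata)."""


class InsufficientDataError(RiverhapError):
    """An estimator was asked to run on too few samples."""


class GeometryError(RiverhapError):
    """Ill-posed geographic computation (e.g. a site lying on a river)."""
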