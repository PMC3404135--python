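"""Exception hierarchy.

Split into input errors (bad files / sequences) and parameter errors
(inconsistent l, d, q, ...) so the CLI can map them to distinct exit codes.
"""


class QmotifError(Exception):
    """Base class for all qmotif errors."""


class InputError(QmotifError):
    """Unreadable or invalid input data (files, sequences, alphabet)."""


class ParameterError(QmotifError):
    """Invalid or inconsistent search parameters."""


class CapacityError(QmotifError):
    """A computation was refused because it would exceed a configured cap."""


class TimeBudgetError(QmotifError):
    """A search exceeded its wall-clock budget and was terminated."""
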