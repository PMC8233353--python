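"""Exception hierarchy for stimlock.

All content errors derive from :class:`StimlockError` so callers can catch
pipeline-level problems without masking programming errors.
"""


class StimlockError(Exception):
    """Base class for all stimlock errors."""


class ParameterError(StimlockError, ValueError):
    """An argument is outside its valid domain (non-positive rate, etc.)."""


class InputError(StimlockError, ValueError):
    """Input data violates a structural precondition (too short, wrong shape)."""


class DegenerateTraceError(StimlockError, ValueError):
    """A trace is constant (or nearly so) where variability is required.

    Signals a dead or saturated ROI whose quietest-window standard deviation
    is below tolerance, or a constant image.
    """

    def __init__(self, message: str, cell_id=None):
        super().__init__(message)
        self.cell_id = cell_id


class ProtocolError(StimlockError, ValueError):
    """The stimulus protocol is inconsistent with the recording."""
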