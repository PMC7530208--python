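"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes so that shell pipelines can
distinguish bad inputs (missing/corrupt files, malformed tables) from
numerical degeneracy (e.g. all calibration points at the same MLSS).
"""


class SludgeColorError(Exception):
    """Base class for all package errors."""


class InputDataError(SludgeColorError):
    """Unreadable, malformed, or out-of-contract input data (CLI exit 3)."""


class DegenerateDataError(SludgeColorError):
    """Input that makes the requested fit or inversion ill-posed (CLI exit 4)."""
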