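"""Exception hierarchy shared across the pipeline stages."""


class PocdkitError(Exception):
    """Base class for all package-specific errors."""


class DataError(PocdkitError):
    """Malformed or schema-violating input data (CSV/TSV/count tables)."""


class CalibrationError(PocdkitError):
    """Control-based RCI calibration cannot be computed (too few controls,
    zero change-score SD, incomplete control scores)."""


class ModelError(PocdkitError):
    """A statistical model cannot be fit (undefined odds ratio, separation,
    rank deficiency, empty margins)."""
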