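"""Exception hierarchy shared across the pipeline."""


class TsPredError(Exception):
    """Base class for all tspred errors."""


class FormatError(TsPredError):
    """A file does not conform to its expected text dialect."""


class IntegrityError(TsPredError):
    """Inputs that parse correctly but violate a cross-record contract
    (duplicate decoy tags, orphan decoys, mismatched term sets, ...)."""


class InsufficientDataError(TsPredError):
    """Too few values to compute the requested statistic."""


class InputError(TsPredError):
    """A caller-supplied value is outside the operation's domain."""


class UndefinedMetricError(TsPredError):
    """A metric is undefined for the given outcome vector
    (e.g. AUROC with a single-class truth vector)."""
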