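"""Exception hierarchy for crtpredict.

Every error raised on a contract violation derives from :class:`CrtPredictError`
so callers can catch the package's failures with a single except clause.
"""


class CrtPredictError(Exception):
    """Base class for all crtpredict errors."""


class ParseError(CrtPredictError):
    """A file could not be parsed (non-numeric or missing cell, bad header)."""


class DuplicateGeneError(ParseError):
    """An expression matrix contains the same gene identifier twice."""


class LabelError(CrtPredictError):
    """A label table is malformed (unknown grade, duplicate sample)."""


class AlignmentError(CrtPredictError):
    """Expression samples and label samples cannot be aligned by id."""


class SpecError(CrtPredictError):
    """A simulation spec is internally inconsistent."""


class StatError(CrtPredictError):
    """A statistical routine received a degenerate input (group too small)."""


class SelectionError(CrtPredictError):
    """A feature/model selection request cannot be satisfied."""


class AlgorithmError(CrtPredictError):
    """Unknown classification algorithm identifier."""


class FeatureError(CrtPredictError):
    """A required feature gene is absent from an expression matrix."""


class TrainError(CrtPredictError):
    """A classifier cannot be trained (e.g. single-class training set)."""


class FoldError(CrtPredictError):
    """Cross-validation folds cannot be formed (class smaller than n_folds)."""


class MatchError(CrtPredictError):
    """Gene-symbol matching between two platforms produced no overlap."""


class ProfileError(CrtPredictError):
    """A quantile profile is invalid or does not fit the data it is applied to."""


class RebuildError(CrtPredictError):
    """Model rebuild on common genes is impossible (empty feature intersection)."""


class EvalError(CrtPredictError):
    """An evaluation metric is undefined for the given confusion matrix."""
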