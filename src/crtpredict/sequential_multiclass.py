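"""Sequential composition of the TO and MI binary predictors.

The three-class rule applies one binary model first; a positive call assigns
its target class, a negative call defers to the second model, and a sample
negative under both is labeled MO (the residual class, which absorbs NT).
The default order applies the TO model first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .classifier_bank import (
    TrainedBinaryModel,
    model_from_dict,
    model_to_dict,
    predict_binary,
)
from .cohort_io import ExpressionMatrix
from .errors import AlgorithmError, TrainError

ORDERS = ("TO_first", "MI_first")
MULTICLASS_LABELS = ("MI", "MO", "TO")

SEQ_FORMAT = "crtpredict-sequential-model"
SEQ_FORMAT_VERSION = 1


@dataclass
class SequentialModel:
    """The two one-vs-rest submodels plus the application order."""

    to_model: TrainedBinaryModel
    mi_model: TrainedBinaryModel
    order: str = "TO_first"

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise AlgorithmError(f"order must be one of {ORDERS}")
        t1 = self.to_model.contrast.target_class
        t2 = self.mi_model.contrast.target_class
        if (t1, t2) != ("TO", "MI"):
            raise TrainError(
                f"submodels must target TO and MI, got {t1!r} and {t2!r}"
            )


def predict_sequential(
    model: SequentialModel, expr: ExpressionMatrix, order: str | None = None
) -> list[str]:
    """Per-sample label in {MI, MO, TO}.

    Under ``TO_first`` a TO-positive sample is labeled TO and the MI model
    is never consulted for it; otherwise MI-positive gives MI and the
    residual label is MO.  ``MI_first`` is the mirror rule.  Each sample's
    label depends only on that sample's expression.
    """
    order = order or model.order
    if order not in ORDERS:
        raise AlgorithmError(f"order must be one of {ORDERS}")
    if order == "TO_first":
        first, second = model.to_model, model.mi_model
    else:
        first, second = model.mi_model, model.to_model
    first_calls = predict_binary(first, expr)
    second_calls = predict_binary(second, expr)
    labels = []
    for c1, c2 in zip(first_calls, second_calls):
        if c1 != "other":
            labels.append(c1)
        elif c2 != "other":
            labels.append(c2)
        else:
            labels.append("MO")
    return labels


def order_agreement(
    model: SequentialModel, expr: ExpressionMatrix
) -> tuple[float, list[str]]:
    """Fraction of samples labeled identically under TO_first and MI_first,
    plus the ids of the disagreeing samples.

    Disagreement is possible only for samples positive under both submodels
    (labeled TO under TO_first, MI under MI_first); this is a diagnostic,
    not an invariant.
    """
    a = predict_sequential(model, expr, order="TO_first")
    b = predict_sequential(model, expr, order="MI_first")
    disagree = [s for s, x, y in zip(expr.sample_ids, a, b) if x != y]
    return 1.0 - len(disagree) / expr.n_samples, disagree


def save_sequential_model(model: SequentialModel, path: str | Path) -> None:
    payload = {
        "format": SEQ_FORMAT,
        "version": SEQ_FORMAT_VERSION,
        "order": model.order,
        "to_model": model_to_dict(model.to_model),
        "mi_model": model_to_dict(model.mi_model),
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_sequential_model(path: str | Path) -> SequentialModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != SEQ_FORMAT:
        raise AlgorithmError(f"not a {SEQ_FORMAT} file")
    return SequentialModel(
        to_model=model_from_dict(payload["to_model"]),
        mi_model=model_from_dict(payload["mi_model"]),
        order=payload["order"],
    )
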