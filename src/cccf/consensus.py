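"""The consensus core: median binarisation and high/low/filtered calling.

Each of the 2k continuous scores per cell (k scorers x 2 signatures) is
binarised at its median over all scored cells: for signature1 a score
strictly above the median maps to 1, otherwise 0; for signature2 the coding
is inverted (above the median maps to 0, otherwise 1), so every bit points
toward the high-risk phenotype. A cell whose bits sum to 2k is called
``high``, a sum of 0 is ``low``, and any intermediate sum is ``filtered``.
Filtered cells are retained with their label so proportion analyses keep
their denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError
from .scoring import ScoreTensor

LABEL_HIGH = "high"
LABEL_LOW = "low"
LABEL_FILTERED = "filtered"

SIGNATURE1 = "signature1"
SIGNATURE2 = "signature2"


@dataclass
class ConsensusResult:
    cell: str
    total: int
    label: str
    bits: np.ndarray  # length 2k, signature1 bits then signature2 bits


def binarize(scores: np.ndarray, direction: str) -> np.ndarray:
    """Binarise one scorer's per-cell scores at their median.

    signature1: score > median -> 1 else 0; signature2: score > median -> 0
    else 1 (strictly-greater comparison; ties at the median fall to the
    "otherwise" branch).
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 2:
        raise DegenerateInputError("binarize needs at least 2 cells")
    if not np.all(np.isfinite(scores)):
        raise DegenerateInputError("scores must be finite")
    if direction not in (SIGNATURE1, SIGNATURE2):
        raise ParameterError(f"unknown direction {direction!r}")
    med = np.median(scores)
    above = scores > med
    if scores.min() == scores.max():
        warnings.warn(
            "all scores identical; every bit takes the 'otherwise' value",
            stacklevel=2,
        )
    if direction == SIGNATURE1:
        return above.astype(np.int8)
    return (~above).astype(np.int8)


def classify(tensor: ScoreTensor) -> list[ConsensusResult]:
    """Median-binarise a full score tensor and call each cell.

    Per-cell totals lie in [0, 2k]; total 2k -> high, 0 -> low, otherwise
    filtered. Medians are computed over all cells jointly.
    """
    k = len(tensor.scorers)
    if k == 0:
        raise ParameterError("classify requires at least one scorer")
    bits1 = np.stack(
        [binarize(tensor.values[:, j, 0], SIGNATURE1) for j in range(k)], axis=1
    )
    bits2 = np.stack(
        [binarize(tensor.values[:, j, 1], SIGNATURE2) for j in range(k)], axis=1
    )
    bits = np.concatenate([bits1, bits2], axis=1)
    totals = bits.sum(axis=1)
    results = []
    for i, cell in enumerate(tensor.cells):
        total = int(totals[i])
        if total == 2 * k:
            label = LABEL_HIGH
        elif total == 0:
            label = LABEL_LOW
        else:
            label = LABEL_FILTERED
        results.append(ConsensusResult(cell=cell, total=total, label=label, bits=bits[i]))
    return results


def results_frame(results: list[ConsensusResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {"total": [r.total for r in results], "label": [r.label for r in results]},
        index=pd.Index([r.cell for r in results], name="cell"),
    )


def proportions(
    results: list[ConsensusResult], group_labels: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-group fractions of high / low / filtered cells (rows sum to 1)."""
    groups = pd.Series(dict(group_labels)) if not isinstance(group_labels, pd.Series) else group_labels
    missing = [r.cell for r in results if r.cell not in groups.index]
    if missing:
        raise ParameterError(f"cells without a group label: {missing[:10]}")
    df = results_frame(results)
    df["group"] = groups.reindex(df.index).array  # .array keeps categoricals
    counts = (
        df.groupby("group", observed=False)["label"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[LABEL_HIGH, LABEL_LOW, LABEL_FILTERED], fill_value=0)
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise DegenerateInputError(f"empty groups: {empty}")
    return counts.div(totals, axis=0)
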