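"""Tissue expression pattern calls with SPM/CTM metrics.

SPM (specificity measurement) of tissue j is the cosine between the
expression vector x and the unit axis of tissue j, i.e. x_j / ‖x‖ with the
Euclidean norm; the squared SPM values sum to 1.  CTM (contribution
measurement) of a tissue subset S is the fraction of the vector's norm
carried by S: ‖x restricted to S‖ / ‖x‖.  A mature miRNA is called
tissue-specific when any SPM exceeds 0.9, else tissue-selective when the
tissues with SPM > 0.5 (at least two) jointly reach CTM > 0.9; anything
else gets no pattern call.  Inputs are normalized (RPM) vectors; both
metrics are invariant to global rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PatternCall:
    mature_id: str
    spm: pd.Series  # per-tissue SPM in [0, 1]
    ctm: float | None  # CTM of the flagged tissue set (selective calls)
    call: str  # "specific" | "selective" | "none"
    tissues: list[str] = field(default_factory=list)


def spm(expression_vector: pd.Series) -> pd.Series:
    """Per-tissue SPM: x_j over the Euclidean norm of the vector."""
    x = expression_vector.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("expression vector must be non-negative")
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("all-zero expression vector: SPM undefined")
    return pd.Series(x / norm, index=expression_vector.index)


def ctm(expression_vector: pd.Series, tissues: list[str]) -> float:
    """Contribution of a tissue subset: norm of the projection over the full norm."""
    x = expression_vector.to_numpy(dtype=float)
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("all-zero expression vector: CTM undefined")
    proj = expression_vector.loc[tissues].to_numpy(dtype=float)
    return float(np.linalg.norm(proj) / norm)


def classify(
    expression_vector: pd.Series,
    mature_id: str = "",
    spm_specific: float = 0.9,
    spm_selective: float = 0.5,
    ctm_threshold: float = 0.9,
) -> PatternCall:
    """Specific/selective/none call for one mature miRNA's tissue profile.

    Specific takes priority: any SPM > 0.9.  Otherwise selective requires
    ≥2 tissues each with SPM > 0.5 whose joint CTM exceeds 0.9.
    """
    s = spm(expression_vector)
    if (s > spm_specific).any():
        top = s.idxmax()
        return PatternCall(mature_id, s, None, "specific", [top])
    cand = [t for t in s.index if s[t] > spm_selective]
    if len(cand) >= 2:
        c = ctm(expression_vector, cand)
        if c > ctm_threshold:
            return PatternCall(mature_id, s, c, "selective", cand)
        return PatternCall(mature_id, s, c, "none", [])
    return PatternCall(mature_id, s, None, "none", [])


def classify_matrix(matrix: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Pattern calls for every row of an entity × tissue matrix."""
    rows = []
    for mature_id, vec in matrix.iterrows():
        if float(vec.sum()) == 0:
            rows.append({"mature_id": mature_id, "call": "undefined", "tissues": ""})
            continue
        call = classify(vec, mature_id=mature_id, **kwargs)
        rows.append(
            {"mature_id": mature_id, "call": call.call, "tissues": ",".join(call.tissues)}
        )
    return pd.DataFrame(rows, columns=["mature_id", "call", "tissues"])
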