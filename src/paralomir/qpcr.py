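"""Comparative-CT (ΔΔCt) relative quantification and preferential-tissue calls.

Relative expression of a target against an endogenous reference (U6 snRNA
for miRNA, 18S rRNA for mRNA): ΔCt = Ct_target − Ct_reference per tissue
and replicate, ΔΔCt = ΔCt_tissue − ΔCt_calibrator, fold = 2^(−ΔΔCt).
Preferential tissues are found by one-way ANOVA on the log2 relative
expression (−ΔΔCt scale, variance-stable) followed by Tukey HSD: a tissue
is flagged when its mean exceeds every non-flagged tissue's mean with an
HSD-significant difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ("tissue", "replicate", "target", "ct")


@dataclass
class CtTable:
    """Replicate-level Ct measurements plus the reference-gene label."""

    rows: pd.DataFrame  # columns: tissue, replicate, target, ct
    reference: str  # e.g. "U6" or "18S"

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"Ct table missing column(s): {missing}")
        if (self.rows["ct"] <= 0).any():
            raise ValueError("Ct values must be positive cycle numbers")


def load_ct_table(path, reference: str) -> CtTable:
    return CtTable(pd.read_csv(path, sep="\t"), reference=reference)


def _delta_ct(ct: CtTable, target: str) -> pd.DataFrame:
    """Per (tissue, replicate) ΔCt = Ct_target − Ct_reference."""
    tgt = ct.rows[ct.rows["target"] == target].set_index(["tissue", "replicate"])["ct"]
    ref = ct.rows[ct.rows["target"] == ct.reference].set_index(["tissue", "replicate"])["ct"]
    missing = set(tgt.index.get_level_values(0)) - set(ref.index.get_level_values(0))
    if missing:
        raise ValueError(f"missing reference {ct.reference!r} Ct for tissue(s): {sorted(missing)}")
    dct = (tgt - ref).dropna().rename("delta_ct").reset_index()
    return dct


def relative_expression(
    ct: CtTable, target: str, calibrator: str | None = None
) -> pd.DataFrame:
    """Per-tissue fold change of a target by the comparative-CT method.

    The calibrator defaults to the tissue with the lowest mean ΔCt (highest
    expression), so all folds are ≤ 1 relative to the peak tissue; folds
    are only interpreted relatively.  Returns one row per tissue with
    mean ΔCt, ΔΔCt and fold = 2^(−ΔΔCt); the calibrator's fold is 1.
    """
    dct = _delta_ct(ct, target)
    mean_dct = dct.groupby("tissue")["delta_ct"].mean()
    if calibrator is None:
        calibrator = mean_dct.idxmin()
    if calibrator not in mean_dct.index:
        raise ValueError(f"calibrator tissue {calibrator!r} absent from Ct table")
    ddct = mean_dct - mean_dct[calibrator]
    out = pd.DataFrame(
        {
            "tissue": mean_dct.index,
            "delta_ct": mean_dct.to_numpy(),
            "delta_delta_ct": ddct.to_numpy(),
            "fold": np.power(2.0, -ddct.to_numpy()),
        }
    ).reset_index(drop=True)
    out.attrs["calibrator"] = calibrator
    return out


def replicate_log2_expression(
    ct: CtTable, target: str, calibrator: str | None = None
) -> pd.DataFrame:
    """Replicate-level −ΔΔCt values (log2 relative expression) for ANOVA."""
    dct = _delta_ct(ct, target)
    mean_dct = dct.groupby("tissue")["delta_ct"].mean()
    if calibrator is None:
        calibrator = mean_dct.idxmin()
    dct["log2_rel"] = -(dct["delta_ct"] - mean_dct[calibrator])
    return dct[["tissue", "replicate", "log2_rel"]]


def preferential_tissues(
    ct: CtTable, target: str, alpha: float = 0.05, calibrator: str | None = None
) -> tuple[set[str], float]:
    """Tissues where the target is preferentially expressed; returns (set, ANOVA p).

    Requires ≥2 tissues with ≥2 replicates each.  If the one-way ANOVA is
    significant at ``alpha``, Tukey HSD pairwise comparisons are run and the
    flagged set is the largest prefix of tissues, ordered by descending
    mean, in which every member's mean exceeds every non-flagged tissue's
    mean with an HSD-significant difference.  (A prefix is required so that
    several jointly elevated tissues — which are not separable from one
    another — can all be flagged together.)
    """
    rep = replicate_log2_expression(ct, target, calibrator=calibrator)
    groups = {t: g["log2_rel"].to_numpy(dtype=float) for t, g in rep.groupby("tissue")}
    if len(groups) < 2:
        raise ValueError("need at least two tissues for ANOVA")
    small = [t for t, v in groups.items() if len(v) < 2]
    if small:
        raise ValueError(f"fewer than 2 replicates in tissue(s): {sorted(small)}")
    labels = sorted(groups)
    samples = [groups[t] for t in labels]
    f_p = float(stats.f_oneway(*samples).pvalue)
    if not (f_p < alpha):
        return set(), f_p
    hsd = stats.tukey_hsd(*samples)
    means = {t: float(np.mean(groups[t])) for t in labels}
    order = sorted(labels, key=lambda t: means[t], reverse=True)
    for k in range(len(order) - 1, 0, -1):
        flagged, rest = order[:k], order[k:]
        if all(
            means[t] > means[u] and hsd.pvalue[labels.index(t), labels.index(u)] < alpha
            for t in flagged
            for u in rest
        ):
            return set(flagged), f_p
    return set(), f_p
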