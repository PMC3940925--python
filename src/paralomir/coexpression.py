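"""Tissue coexpression scoring of major/minor miRNA pairs.

Paralogous precursors share one major mature form, so the major's reads
cannot be attributed to a single precursor directly.  The attribution
statistic used here combines the tissue specificity of the shared major
form with that of each member's distinct minor form.

For the entity × tissue read-count matrix M with row totals T_i and
per-tissue read fractions Q_j (reads in tissue j over all reads), the
tissue specificity of entity i in tissue j is the binomial enrichment
z-statistic, truncated at zero:

    Z_ij = max(0, (M_ij − T_i·Q_j) / sqrt(T_i·Q_j·(1−Q_j)))

i.e. how many standard deviations the observed reads exceed the expectation
under proportional allocation of the entity's reads across tissues.  The
coexpression score of a major/minor pair in tissue j is the product

    S_j = Z_major,j · Z_minor,j

which is large only where both forms are jointly enriched, and exactly 0
whenever the minor form has no reads.  Pairs are screened by keeping the
top decile of scores and then requiring the minor form to be differentially
expressed against every sibling minor within the family by a two-tailed
Fisher exact test (tissue j vs all other tissues).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# relative guard when summing probabilities "as extreme or more extreme",
# protecting float near-ties (same convention as scipy.stats.fisher_exact)
_TIE_EPS = 1 + 1e-7


@dataclass
class CoexpressionInputs:
    """Raw read-count matrix with its marginals, post reads filter.

    ``M`` holds every scored entity (majors and minors) over the common
    tissue set; ``T`` the per-entity totals; ``Q`` the per-tissue read
    fractions computed from the full universe matrix (all miRNAs, not just
    the scored ones); ``kept`` the entities passing the total-reads filter.
    """

    M: pd.DataFrame
    T: pd.Series
    Q: pd.Series
    kept: pd.Index
    min_reads: int = 50


def build_inputs(
    major_matrix: pd.DataFrame,
    minor_matrix: pd.DataFrame,
    universe_matrix: pd.DataFrame,
    min_reads: int = 50,
) -> CoexpressionInputs:
    """Assemble scoring inputs from raw count matrices.

    ``universe_matrix`` defines Q_j and should contain all miRNA rows
    (precursors, majors, minors); the major/minor matrices contribute the
    scored entities.  Entities whose total reads are not strictly above
    ``min_reads`` are excluded from ``kept`` but remain in ``M`` so the
    zero-score bookkeeping of their pairs stays well defined.
    """
    tissues = list(universe_matrix.columns)
    for name, m in (("major", major_matrix), ("minor", minor_matrix)):
        if list(m.columns) != tissues:
            raise ValueError(
                f"{name} matrix tissues {list(m.columns)} do not match universe {tissues}"
            )
    M = pd.concat([major_matrix, minor_matrix[~minor_matrix.index.isin(major_matrix.index)]])
    M = M[~M.index.duplicated(keep="first")].astype(float)
    T = M.sum(axis=1)
    tissue_totals = universe_matrix.sum(axis=0).astype(float)
    grand = float(tissue_totals.sum())
    if grand <= 0:
        raise ValueError("universe matrix has no reads; Q undefined")
    Q = tissue_totals / grand
    kept = M.index[T > min_reads]
    return CoexpressionInputs(M=M, T=T, Q=Q, kept=kept, min_reads=min_reads)


def z_matrix(inputs: CoexpressionInputs) -> pd.DataFrame:
    """Tissue-specificity Z for every entity × tissue, vectorized."""
    M = inputs.M.to_numpy(dtype=float)
    T = inputs.T.to_numpy(dtype=float)[:, None]
    Q = inputs.Q.to_numpy(dtype=float)[None, :]
    expected = T * Q
    var = T * Q * (1.0 - Q)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (M - expected) / np.sqrt(var)
    z = np.where(var > 0, z, 0.0)
    z = np.clip(z, 0.0, None)
    z[M == 0] = 0.0
    return pd.DataFrame(z, index=inputs.M.index, columns=inputs.M.columns)


def specificity_z(inputs: CoexpressionInputs, entity: str, tissue: str) -> float:
    """Z_ij for one entity in one tissue (scalar convenience wrapper)."""
    if entity not in inputs.M.index:
        raise KeyError(f"entity {entity!r} not in coexpression inputs")
    if tissue not in inputs.M.columns:
        raise KeyError(f"tissue {tissue!r} not in coexpression inputs")
    m = float(inputs.M.at[entity, tissue])
    if m == 0:
        return 0.0
    t, q = float(inputs.T[entity]), float(inputs.Q[tissue])
    var = t * q * (1.0 - q)
    if var <= 0:
        return 0.0
    return max(0.0, (m - t * q) / math.sqrt(var))


def coexpression_score(
    inputs: CoexpressionInputs,
    major: str,
    minor: str,
    tissue: str | None = None,
) -> float | pd.Series:
    """S = Z_major · Z_minor per tissue (or for one tissue when given).

    The score is exactly 0 in every tissue when the minor form has no
    reads at all.
    """
    for ent in (major, minor):
        if ent not in inputs.M.index:
            raise KeyError(f"entity {ent!r} not in coexpression inputs")
    zs = z_matrix(inputs)
    s = zs.loc[major] * zs.loc[minor]
    if float(inputs.T[minor]) == 0:
        s = s * 0.0
    if tissue is not None:
        return float(s[tissue])
    return s


def select_top_decile(
    scores: pd.Series, fraction: float = 0.1
) -> pd.DataFrame:
    """Flag the top ``fraction`` of scores, expanding ties at the cutoff.

    Returns a frame with ``rank_percentile`` (share of scores ≥ each score,
    in percent) and ``selected`` (score at or above the ceil(f·N)-th
    highest, and strictly positive — a score of 0 carries no coexpression
    evidence and is never selected).
    """
    n = len(scores)
    if n == 0:
        raise ValueError("no scored pairs to select from")
    vals = scores.to_numpy(dtype=float)
    order = np.sort(vals)[::-1]
    k = max(1, math.ceil(fraction * n))
    cutoff = order[k - 1]
    rank_percentile = pd.Series(
        [100.0 * np.count_nonzero(vals >= v) / n for v in vals], index=scores.index
    )
    selected = (scores >= cutoff) & (scores > 0)
    return pd.DataFrame({"rank_percentile": rank_percentile, "selected": selected})


# ---------------------------------------------------------------------------
# Fisher exact testing of minor forms


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2×2 table [[a, b], [c, d]].

    All-zero tables return 1.0 by convention.
    """
    if a == b == c == d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def fisher_exact_batch(tables: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Fisher exact p-values for an (n, 4) array of tables.

    Tables are rows (a, b, c, d) of [[a, b], [c, d]].  The two-sided p sums
    hypergeometric point probabilities of all tables, with the observed
    margins, that are as likely or less likely than the observed one
    (point-probability method, with a 1e-7 relative tie guard).  Grouping by
    margins means each distinct hypergeometric distribution is evaluated
    once, which is what makes exhaustive sweeps affordable.
    """
    tables = np.asarray(tables, dtype=np.int64)
    if tables.ndim != 2 or tables.shape[1] != 4:
        raise ValueError("tables must have shape (n, 4)")
    a, b, c, d = tables.T
    r1, r2, k = a + b, c + d, a + c
    out = np.ones(len(tables), dtype=float)
    keys = np.stack([r1, r2, k], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    for gi, (R1, R2, K) in enumerate(uniq):
        idx = np.nonzero(inverse == gi)[0]
        N = R1 + R2
        if N == 0:
            out[idx] = 1.0
            continue
        lo, hi = max(0, K - R2), min(K, R1)
        support = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(support, N, R1, K)
        obs = a[idx] - lo
        p = np.array([pmf[pmf <= pmf[o] * _TIE_EPS].sum() for o in obs])
        out[idx] = np.minimum(p, 1.0)
    return out


def fisher_minor_filter(
    family,
    inputs: CoexpressionInputs,
    minor_of: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential expression of sibling minor forms, per tissue.

    For every ordered pair of member minors (A, B) and tissue j the 2×2
    table is [[A reads in j, A reads elsewhere], [B in j, B elsewhere]].
    A member passes in tissue j when p < alpha against every sibling.
    Returns one row per (member, tissue) with the worst-case sibling p.
    """
    members = list(family.members)
    tissues = list(inputs.M.columns)
    rows = []
    tabs = []
    meta = []
    for m_a in members:
        minor_a = minor_of[m_a]
        va = inputs.M.loc[minor_a].to_numpy(dtype=np.int64)
        ta = va.sum()
        for m_b in members:
            if m_b == m_a:
                continue
            minor_b = minor_of[m_b]
            vb = inputs.M.loc[minor_b].to_numpy(dtype=np.int64)
            tb = vb.sum()
            for j, tissue in enumerate(tissues):
                tabs.append((va[j], ta - va[j], vb[j], tb - vb[j]))
                meta.append((m_a, m_b, tissue))
    if not tabs:
        return pd.DataFrame(
            columns=["precursor_id", "tissue", "fisher_p", "fisher_pass", "degenerate"]
        )
    pvals = fisher_exact_batch(np.array(tabs, dtype=np.int64))
    per = pd.DataFrame(meta, columns=["member", "sibling", "tissue"])
    per["p"] = pvals
    per["degenerate"] = [sum(t) == 0 for t in tabs]
    worst = per.groupby(["member", "tissue"], sort=False).agg(
        fisher_p=("p", "max"), degenerate=("degenerate", "any")
    )
    out = worst.reset_index().rename(columns={"member": "precursor_id"})
    out["fisher_pass"] = out["fisher_p"] < alpha
    return out[["precursor_id", "tissue", "fisher_p", "fisher_pass", "degenerate"]]


# ---------------------------------------------------------------------------
# Discrimination report

REPORT_COLUMNS = [
    "family_id", "precursor_id", "major_id", "minor_id", "tissue",
    "z_major", "z_minor", "score", "rank_percentile", "selected_top10",
    "fisher_p", "fisher_pass", "passes", "contributor_call",
]


@dataclass
class CoexpressionReport:
    """Per family × member × tissue scores, filters and contributor calls."""

    rows: pd.DataFrame  # REPORT_COLUMNS
    unresolved: pd.DataFrame  # family_id, reason

    def contributors(self) -> pd.DataFrame:
        """(family_id, tissue, precursor_id) rows where a contributor was called."""
        sub = self.rows[self.rows["contributor_call"]]
        return sub[["family_id", "tissue", "precursor_id"]].reset_index(drop=True)


def discrimination_report(
    families,
    inputs: CoexpressionInputs,
    major_of: dict[str, str],
    minor_of: dict[str, str],
    alpha: float = 0.05,
    top_fraction: float = 0.1,
    correlation_pass: dict[str, bool] | None = None,
) -> CoexpressionReport:
    """Call the contributing precursor per family × tissue.

    ``major_of`` maps family_id to the shared major entity, ``minor_of``
    maps each member precursor to its minor entity (both row labels of the
    inputs matrix).  A member qualifies in a tissue when its pair score is
    in the global top decile and its minor beats every sibling in the
    Fisher screen; among qualifying members the highest score wins.
    Families flagged indistinguishable, or with no qualifying member in any
    tissue, are reported unresolved.  ``correlation_pass`` (precursor →
    bool) optionally pre-excludes members whose major/minor expression was
    not significantly associated.
    """
    zs = z_matrix(inputs)
    tissues = list(inputs.M.columns)
    records = []
    unresolved = []
    fisher_by_family = {}
    for fam in families:
        if fam.indistinguishable:
            unresolved.append((fam.family_id, "indistinguishable: members share minor forms"))
        fisher_by_family[fam.family_id] = fisher_minor_filter(fam, inputs, minor_of, alpha=alpha)
        major = major_of[fam.family_id]
        major_kept = major in inputs.kept
        for member in fam.members:
            minor = minor_of[member]
            scores = coexpression_score(inputs, major, minor)
            excluded = (
                not major_kept
                or (correlation_pass is not None and not correlation_pass.get(member, True))
            )
            for tissue in tissues:
                records.append(
                    {
                        "family_id": fam.family_id,
                        "precursor_id": member,
                        "major_id": major,
                        "minor_id": minor,
                        "tissue": tissue,
                        "z_major": float(zs.at[major, tissue]),
                        "z_minor": float(zs.at[minor, tissue]),
                        "score": float(scores[tissue]) if not excluded else 0.0,
                    }
                )
    rows = pd.DataFrame(records, columns=REPORT_COLUMNS[:8])
    if not len(rows):
        return CoexpressionReport(
            rows=pd.DataFrame(columns=REPORT_COLUMNS),
            unresolved=pd.DataFrame(unresolved, columns=["family_id", "reason"]),
        )

    sel = select_top_decile(rows["score"], fraction=top_fraction)
    rows["rank_percentile"] = sel["rank_percentile"]
    rows["selected_top10"] = sel["selected"]

    fisher_all = pd.concat(
        [f.assign(family_id=fid) for fid, f in fisher_by_family.items()], ignore_index=True
    )
    rows = rows.merge(
        fisher_all[["family_id", "precursor_id", "tissue", "fisher_p", "fisher_pass"]],
        on=["family_id", "precursor_id", "tissue"],
        how="left",
    )
    rows["fisher_p"] = rows["fisher_p"].fillna(1.0)
    rows["fisher_pass"] = rows["fisher_pass"].fillna(False).astype(bool)
    rows["passes"] = rows["selected_top10"] & rows["fisher_pass"]

    indist = {f.family_id for f in families if f.indistinguishable}
    rows["contributor_call"] = False
    for (fid, tissue), grp in rows.groupby(["family_id", "tissue"], sort=False):
        if fid in indist:
            continue
        qual = grp[grp["passes"]]
        if len(qual):
            winner = qual["score"].idxmax()
            rows.loc[winner, "contributor_call"] = True

    called = set(rows.loc[rows["contributor_call"], "family_id"])
    for fam in families:
        if fam.family_id not in called and fam.family_id not in indist:
            unresolved.append((fam.family_id, "no member passed the selection filters"))
    return CoexpressionReport(
        rows=rows[REPORT_COLUMNS],
        unresolved=pd.DataFrame(unresolved, columns=["family_id", "reason"]),
    )


def score_pair_matrix(
    inputs: CoexpressionInputs, pair_a: str, pair_b: str
) -> pd.Series:
    """Coexpression score of an arbitrary mature pair for the cluster screen.

    The same statistic applies to clustered mature miRNAs: high scores in a
    tissue mean both cluster members are jointly enriched there.
    """
    return coexpression_score(inputs, pair_a, pair_b)
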