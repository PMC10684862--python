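"""Per-sample gene-set scoring and microenvironment characterization.

Single-sample scores are rank-based (ssGSEA-style): within each sample the
genes are ranked, and a set's score integrates the gap between the weighted
in-set rank ECDF and the uniform out-of-set ECDF.  Rank-based scoring stays
well defined under the heavy ties of 0/1 data, where kernel-density scoring
degenerates.  Immune/stromal signature scores feed the purity mapping
purity = cos(0.6049872018 + 0.0001467884 * combined_score), the published
transcriptome-based calibration of tumor purity against a combined
immune+stromal score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import BinaryMatrix, ExpressionMatrix

PURITY_A = 0.6049872018
PURITY_B = 0.0001467884


def _as_matrix(values, genes=None) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(values, (BinaryMatrix, ExpressionMatrix)):
        return values.values.astype(float), list(values.genes), list(values.samples)
    arr = np.asarray(values, dtype=float)
    g = genes if genes is not None else [f"g{i}" for i in range(arr.shape[0])]
    s = [f"s{i}" for i in range(arr.shape[1])]
    return arr, g, s


def ssgsea(
    values, gene_set: list[str], alpha: float = 0.25, genes: list[str] | None = None
) -> pd.Series:
    """ssGSEA-style per-sample enrichment of one gene set.

    Per sample: genes get average ranks (ascending, ties averaged); walking
    down the decreasing-rank order, the score accumulates the difference
    between the weighted in-set ECDF (weights rank^alpha) and the uniform
    out-of-set ECDF.  alpha=0 reduces to an unweighted ECDF difference.
    """
    mat, gene_names, samples = _as_matrix(values, genes)
    pos = {g: i for i, g in enumerate(gene_names)}
    members = [pos[g] for g in gene_set if g in pos]
    if not members:
        raise ValueError("gene set has no members in the matrix")
    n_genes = mat.shape[0]
    in_set = np.zeros(n_genes, dtype=bool)
    in_set[members] = True
    n_out = n_genes - in_set.sum()
    if n_out == 0:
        raise ValueError("gene set covers every gene; score undefined")
    scores = np.empty(mat.shape[1])
    for j in range(mat.shape[1]):
        ranks = stats.rankdata(mat[:, j], method="average")
        order = np.argsort(-ranks, kind="stable")
        hit = in_set[order]
        w = ranks[order] ** alpha
        hit_w = np.where(hit, w, 0.0)
        ecdf_in = np.cumsum(hit_w) / hit_w.sum()
        ecdf_out = np.cumsum(~hit) / n_out
        scores[j] = float((ecdf_in - ecdf_out).sum())
    return pd.Series(scores, index=samples)


def estimate_scores(
    values,
    immune_signature: list[str],
    stromal_signature: list[str],
    alpha: float = 0.25,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Immune/stromal signature scores, their sum, and derived tumor purity."""
    if not immune_signature or not stromal_signature:
        raise ValueError("both signatures must be nonempty")
    immune = ssgsea(values, immune_signature, alpha=alpha, genes=genes)
    stromal = ssgsea(values, stromal_signature, alpha=alpha, genes=genes)
    combined = immune + stromal
    purity = np.clip(np.cos(PURITY_A + PURITY_B * combined), 0.0, 1.0)
    return pd.DataFrame(
        {
            "immune_score": immune,
            "stromal_score": stromal,
            "estimate_score": combined,
            "tumor_purity": purity,
        }
    )


def marker_scores(
    values, marker_sets: dict[str, list[str]], genes: list[str] | None = None
) -> pd.DataFrame:
    """Mean marker-gene expression per cell population (proportion of 1s on 0/1 data).

    Populations whose markers are entirely absent from the matrix are
    omitted (flagged via the returned frame's columns).
    """
    mat, gene_names, samples = _as_matrix(values, genes)
    pos = {g: i for i, g in enumerate(gene_names)}
    out = {}
    for name, members in marker_sets.items():
        idx = [pos[g] for g in members if g in pos]
        if not idx:
            continue
        out[name] = mat[idx, :].mean(axis=0)
    return pd.DataFrame(out, index=samples)


def wilcoxon_compare(
    values: np.ndarray | pd.Series, groups: np.ndarray | list
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum between the two groups in ``groups``.

    Exact null for combined n <= 25 without ties; otherwise the normal
    approximation with tie and continuity corrections.  Returns
    (Mann-Whitney U of the first group, two-sided p).
    """
    v = np.asarray(pd.Series(values).to_numpy(), dtype=float)
    g = np.asarray(groups)
    uniq = sorted(pd.unique(g).tolist())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    x = v[g == uniq[0]]
    y = v[g == uniq[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        # Degenerate: no ordering information at all.
        return float(len(x) * len(y) / 2.0), 1.0
    method = "exact" if (len(pooled) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def checkpoint_compare(
    cohorts: list[ExpressionMatrix],
    labels: dict[str, str],
    genes: tuple[str, ...] = ("PDCD1", "CTLA4"),
    prefixed: bool = True,
) -> pd.DataFrame:
    """Per-cohort subtype comparison of checkpoint-gene expression.

    Uses the *continuous* (pre-binarization) values, cohort by cohort —
    never pooled, since raw scales differ across cohorts.  ``labels`` maps
    (prefixed) sample ids to subtypes; cohorts are compared only over their
    labelled samples.  Genes absent from a cohort yield a row with
    missing=True.
    """
    rows = []
    for m in cohorts:
        ids = [f"{m.cohort_id}_{s}" if prefixed else s for s in m.samples]
        keep = [i for i, sid in enumerate(ids) if sid in labels]
        grp = np.array([labels[ids[i]] for i in keep])
        pos = {g: i for i, g in enumerate(m.genes)}
        for gene in genes:
            if gene not in pos:
                rows.append(
                    {
                        "cohort": m.cohort_id, "gene": gene, "missing": True,
                        "n_ox": 0, "n_im": 0, "statistic": np.nan, "p": np.nan,
                        "higher_in": pd.NA,
                    }
                )
                continue
            vals = m.values[pos[gene], keep]
            n_ox = int((grp == "OX+").sum())
            n_im = int((grp == "IM+").sum())
            if n_ox == 0 or n_im == 0:
                stat, p, higher = np.nan, np.nan, pd.NA
            else:
                stat, p = wilcoxon_compare(vals, grp)
                med_im = np.median(vals[grp == "IM+"])
                med_ox = np.median(vals[grp == "OX+"])
                higher = "IM+" if med_im > med_ox else ("OX+" if med_ox > med_im else "tie")
            rows.append(
                {
                    "cohort": m.cohort_id, "gene": gene, "missing": False,
                    "n_ox": n_ox, "n_im": n_im, "statistic": stat, "p": p,
                    "higher_in": higher,
                }
            )
    return pd.DataFrame(rows)
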