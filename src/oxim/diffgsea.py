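"""Differential analysis on binary expression and preranked enrichment.

After median binarization the per-gene data are Bernoulli, so differential
"expression" between subtypes reduces to comparing the within-subtype
proportions of high (1) calls: a two-sided Fisher exact test on the 2x2
(subtype x {0,1}) table, with a fold change defined on the smoothed
proportion ratio, log2((p_A + eps) / (p_B + eps)).  Pathway-level structure
is read off a preranked GSEA: genes are ordered by fold change and each
set's enrichment score is the maximum deviation of a weighted
Kolmogorov-Smirnov running sum, normalized against a null of random
same-size gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohorts import BinaryMatrix

#: Pseudo-proportion added to both arms of the fold-change ratio.
FC_EPS = 0.01


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binary_de(
    b: BinaryMatrix | np.ndarray,
    labels: list[str] | np.ndarray,
    group_order: tuple[str, str] | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene Fisher exact test + proportion-ratio log2 fold change.

    ``group_order = (A, B)`` fixes the fold-change direction: positive
    log2fc means the gene is high more often in A.  Defaults to the sorted
    label values.  Returns a DataFrame with columns
    gene / log2fc / p / p_adj / prop_high_a / prop_high_b.
    """
    if isinstance(b, BinaryMatrix):
        values, gene_names = b.values, b.genes
    else:
        values = np.asarray(b)
        gene_names = genes if genes is not None else [f"g{i}" for i in range(values.shape[0])]
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two label values, got {uniq}")
    if group_order is None:
        group_order = (uniq[0], uniq[1])
    a_mask = labels == group_order[0]
    b_mask = labels == group_order[1]
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("each group needs at least two samples")

    n_a, n_b = int(a_mask.sum()), int(b_mask.sum())
    ones_a = values[:, a_mask].sum(axis=1).astype(int)
    ones_b = values[:, b_mask].sum(axis=1).astype(int)
    p_a = ones_a / n_a
    p_b = ones_b / n_b
    log2fc = np.log2((p_a + FC_EPS) / (p_b + FC_EPS))
    pvals = np.array(
        [
            stats.fisher_exact(
                [[oa, n_a - oa], [ob, n_b - ob]], alternative="two-sided"
            )[1]
            for oa, ob in zip(ones_a, ones_b)
        ]
    )
    return pd.DataFrame(
        {
            "gene": gene_names,
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": bh_adjust(pvals),
            "prop_high_a": p_a,
            "prop_high_b": p_b,
        }
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Duplicate members within a set are dropped (order preserved).
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            seen: dict[str, None] = {}
            for g in fields[2:]:
                if g and g not in seen:
                    seen[g] = None
            sets[name] = list(seen)
    return sets


def make_ranking(diff: pd.DataFrame) -> pd.Series:
    """Ranking statistic for preranked GSEA: log2fc, ties by smaller p then name."""
    ordered = diff.sort_values(
        ["log2fc", "p", "gene"], ascending=[False, True, True], kind="mergesort"
    )
    return pd.Series(ordered["log2fc"].to_numpy(), index=ordered["gene"].to_numpy())


def enrichment_score(
    stats_sorted: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0
) -> float:
    """Weighted KS enrichment score of one set against a sorted ranking.

    ``stats_sorted`` must be in decreasing order; ``hit_mask`` flags set
    members.  Hits advance the running sum proportionally to |stat|^weight,
    misses retreat it by 1/(N - Nh); the ES is the running-sum value of
    largest magnitude.
    """
    N = len(stats_sorted)
    nh = int(hit_mask.sum())
    if nh == 0 or nh == N:
        raise ValueError("set must be a proper nonempty subset of the ranking")
    w = np.abs(stats_sorted) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all member stats are zero: fall back to unweighted hits
        hit_w = hit_mask.astype(float)
        denom = float(nh)
    steps = hit_w / denom - (~hit_mask) / (N - nh)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


@dataclass
class EnrichmentRecord:
    name: str
    es: float
    nes: float
    p: float
    size: int


def gsea_preranked(
    ranking: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 10_000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA over a named gene-set collection.

    The null distribution for each set size is built by drawing ``n_perm``
    random same-size gene sets from the ranking (gene-set permutation).
    NES = ES / mean |null ES| of the matching sign; p is the one-sided tail
    frequency with +1 smoothing; BH adjustment across sets.  Sets with no
    ranked members are skipped; sets whose matching-sign null is empty are
    flagged undefined (NES = nan) and excluded from the BH adjustment.
    """
    ranking = ranking.sort_values(ascending=False, kind="mergesort")
    gene_index = {g: i for i, g in enumerate(ranking.index)}
    stats_sorted = ranking.to_numpy(dtype=float)
    N = len(stats_sorted)
    rng = np.random.default_rng(seed)

    sizes = sorted(
        {
            len([g for g in members if g in gene_index])
            for members in sets.values()
        }
        - {0, N}
    )
    null_by_size: dict[int, np.ndarray] = {}
    for size in sizes:
        null = np.empty(n_perm)
        for j in range(n_perm):
            idx = rng.choice(N, size=size, replace=False)
            mask = np.zeros(N, dtype=bool)
            mask[idx] = True
            null[j] = enrichment_score(stats_sorted, mask, weight)
        null_by_size[size] = null

    rows = []
    for name, members in sets.items():
        present = [g for g in members if g in gene_index]
        if not present or len(present) >= N:
            continue
        mask = np.zeros(N, dtype=bool)
        mask[[gene_index[g] for g in present]] = True
        es = enrichment_score(stats_sorted, mask, weight)
        null = null_by_size[len(present)]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign) == 0 or np.abs(same_sign).mean() == 0:
            nes, p = np.nan, np.nan
        else:
            nes = es / np.abs(same_sign).mean()
            p = (1 + (np.abs(same_sign) >= abs(es)).sum()) / (1 + len(same_sign))
        rows.append({"name": name, "es": es, "nes": nes, "p": p, "size": len(present)})
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["name", "es", "nes", "p", "p_adj", "size"])
    out["p_adj"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out[["name", "es", "nes", "p", "p_adj", "size"]]


def label_subtypes(
    enrichment: pd.DataFrame,
    ox_marker_sets: list[str],
    im_marker_sets: list[str],
    cluster_names: tuple[str, str] = ("A", "B"),
) -> dict[str, str]:
    """Decide which of two clusters is OX+ from signed enrichment.

    ``enrichment`` is the table for cluster A vs cluster B (positive NES =
    enriched in A).  A positive mean NES over the oxidative marker sets
    makes A the OX+ cluster; ties fall back to the immune markers with
    opposite sign.
    """
    idx = enrichment.set_index("name")
    missing = [s for s in list(ox_marker_sets) + list(im_marker_sets) if s not in idx.index]
    if missing:
        raise ValueError(f"marker sets absent from enrichment results: {missing}")
    ox_mean = float(idx.loc[list(ox_marker_sets), "nes"].mean())
    im_mean = float(idx.loc[list(im_marker_sets), "nes"].mean())
    a, b = cluster_names
    score = ox_mean if ox_mean != 0 else -im_mean
    if score >= 0:
        return {a: "OX+", b: "IM+"}
    return {a: "IM+", b: "OX+"}
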