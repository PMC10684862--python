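"""Consensus clustering of binary expression profiles.

Stability-based subtype discovery: repeatedly subsample the samples, cluster
each subset with PAM (k-medoids) under Pearson-correlation distance, and
record how often each pair of samples lands in the same cluster among the
resamples in which both were drawn.  The resulting consensus matrix (entries
in [0, 1]) is itself clustered (average-linkage on 1 - consensus) to produce
the final subtype labels.

PAM is implemented here directly (BUILD + SWAP) because no installed library
provides it; the SWAP phase is vectorized over candidate swaps via the
precomputed distance matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohorts import BinaryMatrix


def pearson_distance(b: BinaryMatrix | np.ndarray) -> np.ndarray:
    """Pairwise d(i,j) = 1 - Pearson r between sample gene-vectors.

    Values lie in [0, 2].  If either vector has zero variance, r is
    undefined; the convention d = 1 (the value for uncorrelated vectors)
    keeps the distance defined on degenerate profiles.
    """
    values = b.values if isinstance(b, BinaryMatrix) else np.asarray(b, dtype=float)
    n = values.shape[1]
    if n < 2:
        raise ValueError("need at least two samples")
    X = values.astype(float).T  # samples x genes
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    R = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    np.clip(R, -1.0, 1.0, out=R)
    d = 1.0 - R
    if zero.any():
        d[zero, :] = 1.0
        d[:, zero] = 1.0
    np.fill_diagonal(d, 0.0)
    return d


def _assign(d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Assign each point to its nearest medoid (ties -> lowest medoid index)."""
    sub = d[np.ix_(np.arange(d.shape[0]), medoids)]
    labels = np.argmin(sub, axis=1)  # argmin takes the first minimum: tie rule
    cost = float(sub[np.arange(d.shape[0]), labels].sum())
    return labels, cost


def pam(
    d: np.ndarray, k: int, seed: int = 0, restarts: int = 2
) -> tuple[np.ndarray, np.ndarray, float]:
    """Partitioning Around Medoids: greedy BUILD then best-improvement SWAP.

    BUILD adds medoids one at a time, each minimizing the resulting total
    cost.  SWAP repeatedly applies the single (medoid, non-medoid) exchange
    that most reduces total cost, until no exchange strictly improves it.
    BUILD+SWAP is a heuristic that can stop in a local optimum requiring a
    double exchange to escape; ``restarts`` extra SWAP passes from seeded
    random medoid sets are run and the best solution kept.  Returns
    (labels, medoid indices, total cost); deterministic under ``seed``.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        # Cost after adding candidate j: sum_i min(nearest_i, d_ij).
        gains = np.minimum(nearest[:, None], d).sum(axis=0)
        gains[medoids] = np.inf
        j = int(np.argmin(gains))
        medoids.append(j)
        nearest = np.minimum(nearest, d[:, j])
    best = _swap_to_convergence(d, np.sort(np.array(medoids)), k)
    rng = np.random.default_rng(seed)
    for _ in range(max(0, restarts)):
        init = np.sort(rng.choice(n, size=k, replace=False))
        cand = _swap_to_convergence(d, init, k)
        if cand[2] < best[2] - 1e-12:
            best = cand
    labels, medoids_arr, cost = best
    return labels, medoids_arr, cost


def _swap_to_convergence(
    d: np.ndarray, medoids_arr: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, float]:
    n = d.shape[0]
    _, cost = _assign(d, medoids_arr)
    while True:
        sub = d[:, medoids_arr]
        order = np.argsort(sub, axis=1, kind="stable")
        near_val = sub[np.arange(n), order[:, 0]]
        if k > 1:
            second_val = sub[np.arange(n), order[:, 1]]
        else:
            second_val = np.full(n, np.inf)
        near_idx = order[:, 0]
        best_delta, best_swap = 0.0, None
        for mi, m in enumerate(medoids_arr):
            # Distance to nearest medoid if m were removed.
            base = np.where(near_idx == mi, second_val, near_val)
            # New cost for every candidate h: sum_i min(d_ih, base_i).
            new_costs = np.minimum(d, base[:, None]).sum(axis=0)
            new_costs[medoids_arr] = np.inf
            h = int(np.argmin(new_costs))
            delta = new_costs[h] - cost
            if delta < best_delta - 1e-12:
                best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids_arr = np.sort(np.concatenate([np.delete(medoids_arr, mi), [h]]))
        _, cost = _assign(d, medoids_arr)
    labels, cost = _assign(d, medoids_arr)
    return labels, medoids_arr, cost



@dataclass
class ConsensusResult:
    """Output of a consensus-clustering run."""

    k: int
    reps: int
    p_item: float
    seed: int
    samples: list[str]
    consensus: np.ndarray  # samples x samples, entries in [0, 1]
    co_sample_counts: np.ndarray  # times each pair was drawn together
    labels: np.ndarray  # integer cluster per sample, 0..k-1

    def write(self, outdir: str | Path, prefix: str = "consensus") -> None:
        outdir = Path(outdir)
        df = pd.DataFrame(self.consensus, index=self.samples, columns=self.samples)
        df.index.name = "sample_id"
        df.to_csv(outdir / f"{prefix}_matrix.tsv", sep="\t", float_format="%.6g")
        pd.DataFrame({"sample_id": self.samples, "cluster": self.labels}).to_csv(
            outdir / f"{prefix}_labels.tsv", sep="\t", index=False
        )
        (outdir / f"{prefix}_params.json").write_text(
            json.dumps(
                {"k": self.k, "reps": self.reps, "p_item": self.p_item, "seed": self.seed},
                indent=1,
            )
        )


def assign_from_consensus(consensus: np.ndarray, k: int) -> np.ndarray:
    """Cut an average-linkage tree on (1 - consensus) into k groups (labels 0..k-1)."""
    n = consensus.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    diss = 1.0 - np.asarray(consensus, dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    Z = linkage(squareform(diss, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def consensus_cluster(
    b: BinaryMatrix | np.ndarray,
    k: int = 2,
    reps: int = 100,
    p_item: float = 0.8,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> ConsensusResult:
    """Resampled PAM under Pearson distance; consensus matrix + labels.

    Each of ``reps`` iterations draws floor(p_item * n) samples without
    replacement and clusters them; consensus[i, j] is the fraction of
    co-draws in which i and j were co-clustered (0 where never co-drawn).
    """
    if isinstance(b, BinaryMatrix):
        values = b.values.astype(float)
        samples = list(b.samples)
    else:
        values = np.asarray(b, dtype=float)
        samples = sample_ids if sample_ids is not None else [f"s{i}" for i in range(values.shape[1])]
    n = values.shape[1]
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0 < p_item <= 1:
        raise ValueError("p_item must lie in (0, 1]")
    m = int(np.floor(p_item * n))
    if m < k:
        raise ValueError(f"subsample size {m} smaller than k={k}")
    rng = np.random.default_rng(seed)
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        d = pearson_distance(values[:, idx])
        lab, _, _ = pam(d, k)
        co_sample[np.ix_(idx, idx)] += 1
        same = lab[:, None] == lab[None, :]
        co_cluster[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    labels = assign_from_consensus(consensus, k)
    return ConsensusResult(
        k=k,
        reps=reps,
        p_item=p_item,
        seed=seed,
        samples=samples,
        consensus=consensus,
        co_sample_counts=co_sample.astype(int),
        labels=labels,
    )
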