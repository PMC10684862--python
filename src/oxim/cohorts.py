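"""Cohort ingestion, median binarization, merging, splitting, and batch diagnostics.

Expression from different cohorts (platforms, labs, normalizations) cannot be
pooled directly: cohort-specific location/scale shifts dominate any biology.
The integration strategy here is deliberately blunt — within each cohort,
every gene is thresholded at its own median, so a sample's value becomes
"above (1) or below (0) the cohort-typical level of this gene".  Any
per-(gene, cohort) monotone distortion is erased by construction, which is
why the merged 0/1 matrix mixes cohorts where the raw values do not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score


class ParseError(ValueError):
    """Raised when an expression or clinical file cannot be interpreted."""


class MergeError(ValueError):
    """Raised when cohorts cannot be merged (e.g. empty gene intersection)."""


@dataclass
class ExpressionMatrix:
    """Continuous genes x samples matrix for a single cohort."""

    cohort_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class BinaryMatrix:
    """0/1 genes x samples matrix with per-sample cohort provenance.

    ``thresholds`` retains the per-(gene, cohort) medians used for the
    transformation, keyed by cohort id, for logging/round-tripping.
    """

    genes: list[str]
    samples: list[str]
    cohorts: list[str]  # cohort id of each sample, parallel to ``samples``
    values: np.ndarray  # shape (n_genes, n_samples), entries in {0, 1}
    thresholds: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("binary matrix shape inconsistent with labels")
        if len(self.cohorts) != len(self.samples):
            raise ValueError("cohort labels must parallel samples")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            raise ValueError("binary matrix contains values outside {0, 1}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def subset_samples(self, sample_ids: list[str]) -> "BinaryMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return BinaryMatrix(
            genes=list(self.genes),
            samples=list(sample_ids),
            cohorts=[self.cohorts[i] for i in idx],
            values=self.values[:, idx],
            thresholds=self.thresholds,
        )

    def write(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")
        if sidecar is not None:
            meta = {
                "cohorts": dict(zip(self.samples, self.cohorts)),
                "thresholds": self.thresholds,
            }
            Path(sidecar).write_text(json.dumps(meta, indent=1, sort_keys=True))


CLINICAL_COLUMNS = [
    "sample_id",
    "cohort",
    "os_time_years",
    "os_event",
    "age",
    "sex",
    "t_stage",
    "n_stage",
    "m_stage",
]


def validate_clinical(clin: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical-table contract: unique ids, valid time/event."""
    missing = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
    if missing:
        raise ParseError(f"clinical table missing columns: {missing}")
    if clin["sample_id"].duplicated().any():
        dupes = clin.loc[clin["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"duplicate sample ids in clinical table: {dupes[:5]}")
    if (clin["os_time_years"] < 0).any():
        raise ParseError("negative survival times")
    if not clin["os_event"].isin([0, 1]).all():
        raise ParseError("os_event must be 0/1")
    return clin


def read_clinical(path: str | Path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t", na_values=["NA"])
    return validate_clinical(clin)


def read_expression(path: str | Path, cohort_id: str | None = None) -> ExpressionMatrix:
    """Read a tab-delimited genes x samples table.

    First column holds gene symbols, header row holds sample ids.  Duplicate
    gene rows are collapsed by their mean so each symbol gets one threshold
    downstream.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: no data rows/columns")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ParseError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
    if df.index.duplicated().any():
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(
        cohort_id=cohort_id if cohort_id is not None else path.stem,
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def binarize(m: ExpressionMatrix) -> BinaryMatrix:
    """Median-threshold every gene within its cohort.

    A value maps to 1 iff it is *strictly* greater than that gene's
    within-cohort median (midpoint of the two central order statistics for
    even n).  Constant genes therefore become all-zero.
    """
    if m.n_genes == 0 or m.n_samples == 0:
        raise ValueError("cannot binarize an empty matrix")
    med = np.median(m.values, axis=1)
    values = (m.values > med[:, None]).astype(np.int8)
    thresholds = {m.cohort_id: {g: float(t) for g, t in zip(m.genes, med)}}
    return BinaryMatrix(
        genes=list(m.genes),
        samples=list(m.samples),
        cohorts=[m.cohort_id] * m.n_samples,
        values=values,
        thresholds=thresholds,
    )


def merge(cohorts: list[BinaryMatrix], prefix_samples: bool = True) -> BinaryMatrix:
    """Merge binarized cohorts on their shared genes.

    The gene set of the merged matrix is the intersection across cohorts
    (kept in the first cohort's order); samples are concatenated and made
    unique with a ``<cohort>_`` prefix.
    """
    if len(cohorts) < 2:
        raise MergeError("need at least two cohorts to merge")
    shared = set(cohorts[0].genes)
    for c in cohorts[1:]:
        shared &= set(c.genes)
    if not shared:
        counts = {c.cohorts[0]: c.n_genes for c in cohorts}
        raise MergeError(f"empty gene intersection; per-cohort gene counts: {counts}")
    genes = [g for g in cohorts[0].genes if g in shared]

    blocks, samples, labels = [], [], []
    thresholds: dict[str, dict[str, float]] = {}
    for c in cohorts:
        pos = {g: i for i, g in enumerate(c.genes)}
        blocks.append(c.values[[pos[g] for g in genes], :])
        cid = c.cohorts[0]
        if prefix_samples:
            samples.extend(f"{cid}_{s}" for s in c.samples)
        else:
            samples.extend(c.samples)
        labels.extend(c.cohorts)
        for cohort_id, th in c.thresholds.items():
            thresholds[cohort_id] = {g: th[g] for g in genes if g in th}
    return BinaryMatrix(
        genes=genes,
        samples=samples,
        cohorts=labels,
        values=np.concatenate(blocks, axis=1),
        thresholds=thresholds,
    )


def split(
    b: BinaryMatrix,
    clin: pd.DataFrame,
    fraction: float = 0.5,
    seed: int = 0,
) -> tuple[tuple[BinaryMatrix, pd.DataFrame], tuple[BinaryMatrix, pd.DataFrame]]:
    """Random, unstratified partition of samples into two halves.

    The first part receives round(n * fraction) samples.  The partition is
    disjoint, exhaustive, and a pure function of the seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    clin_ids = set(clin["sample_id"])
    missing = [s for s in b.samples if s not in clin_ids]
    if missing:
        raise ValueError(f"clinical table missing samples: {missing[:5]}")
    n = b.n_samples
    n_first = int(round(n * fraction))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    first_ids = [b.samples[i] for i in sorted(order[:n_first])]
    second_ids = [b.samples[i] for i in sorted(order[n_first:])]

    def _part(ids: list[str]) -> tuple[BinaryMatrix, pd.DataFrame]:
        sub = b.subset_samples(ids)
        sub_clin = clin.set_index("sample_id").loc[ids].reset_index()
        return sub, sub_clin

    return _part(first_ids), _part(second_ids)


def batch_silhouette(
    values: np.ndarray,
    cohort_labels: list[str],
    scale: bool = False,
    seed: int = 0,
) -> float:
    """Mean silhouette of cohort labels in the top-2 principal-component plane.

    Quantifies how separable cohorts are: ~0 when cohorts mix (no batch
    effect visible), near 1 when each cohort forms its own cloud.  Input is
    genes x samples; binary input is centered only, continuous input may be
    standardized per gene (``scale=True``).
    """
    labels = np.asarray(cohort_labels)
    if len(set(labels)) < 2:
        raise ValueError("need at least two cohorts")
    X = np.asarray(values, dtype=float).T  # samples x genes
    if X.shape[0] < 3:
        raise ValueError("need at least three samples")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    coords = PCA(n_components=2, random_state=seed).fit_transform(X)
    return float(silhouette_score(coords, labels, metric="euclidean"))
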