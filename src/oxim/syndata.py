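"""Synthetic multi-cohort expression, clinical, and survival data.

Emulates the structure of a multi-study lung-adenocarcinoma compendium:
many cohorts of unequal size, strong cohort-specific location/scale batch
effects, partially overlapping gene inventories, and two latent tumor
subtypes — an oxidative/proliferative subtype (OX+, worse prognosis) and an
immune-infiltrated subtype (IM+) — that shift the expression of two disjoint
gene programs.  Ground truth (subtype per sample, informative genes) is
returned alongside the data so recovery can be measured.

Expression model
----------------
Gene g in sample s of cohort c:

    x_gs = scale_cg * (mu_g + beta_g * z_s + eps_gs) + shift_cg

with z_s the OX+ indicator (for OX-program genes; the IM+ indicator for
IM-program genes), eps ~ N(0, 1), shift_cg ~ N(0, batch_mu_sd^2) and
log(scale_cg) ~ N(0, batch_scale_sd^2).  Because the batch transform is
monotone per (gene, cohort), within-cohort median thresholding removes it
exactly; the raw data, by contrast, separates by cohort in PC space.

``beta_g`` is calibrated from ``delta_p``, the target difference in the
probability of being called "high" (above the cohort median) between
subtypes: with prevalence 1/2 and unit noise, beta = 2 * Phi^-1((1+delta_p)/2).

Survival is exponential with hazard ``baseline_hazard`` for IM+ samples and
``baseline_hazard * hazard_ratio`` for OX+ samples, with independent
exponential censoring whose rate is set so that the expected censored
fraction equals ``censor_rate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import CLINICAL_COLUMNS, ExpressionMatrix

# Named RNG substreams: each stage derives its own generator from
# (seed, stream id), so adding a stage never perturbs earlier draws.
_STREAMS = {
    "structure": 1,
    "expression": 2,
    "survival": 3,
    "censoring": 4,
    "clinical": 5,
}

#: Cohort sizes of the emulated 12-study compendium (11 public microarray
#: cohorts plus one RNA-seq cohort), totalling 2154 samples.
STUDY_COHORT_SIZES = [58, 117, 71, 115, 85, 226, 106, 182, 133, 127, 442, 492]

#: 12 oxidative/proliferative marker genes used as the head of the default
#: OX program (the remainder are synthetic OXG* symbols).
OX_PANEL_GENES = [
    "ACP1", "AURKA", "BIRC5", "CYC1", "GSTP1", "HSPD1",
    "HSPE1", "MDH2", "MRPL13", "NDUFS1", "SNRPD1", "SORD",
]

#: Immune checkpoint / effector genes heading the default IM program.
IM_MARKER_GENES = ["PDCD1", "CTLA4", "CD8A", "GZMB", "IFNG", "CD274"]


class InvalidConfigError(ValueError):
    """Raised when a SynthConfig violates its invariants."""


def _default_programs(n_per_program: int = 40) -> tuple[list[str], list[str]]:
    ox = OX_PANEL_GENES + [f"OXG{i:03d}" for i in range(len(OX_PANEL_GENES) + 1, n_per_program + 1)]
    im = IM_MARKER_GENES + [f"IMG{i:03d}" for i in range(len(IM_MARKER_GENES) + 1, n_per_program + 1)]
    return ox, im


@dataclass
class SynthConfig:
    """Parameters of the synthetic compendium.

    Defaults reproduce the emulated study conditions: 12 cohorts sized
    58-492 (2154 samples), two 40-gene programs, a high-call probability
    shift of 0.4 between subtypes, unit-scale batch shifts, hazard ratio 2
    for the OX+ subtype, and ~30% censoring.
    """

    cohort_sizes: list[int] = field(default_factory=lambda: list(STUDY_COHORT_SIZES))
    n_genes: int = 500
    n_shared_genes: int = 400
    ox_program: list[str] = field(default_factory=lambda: _default_programs()[0])
    im_program: list[str] = field(default_factory=lambda: _default_programs()[1])
    delta_p: float = 0.4
    batch_mu_sd: float = 1.0
    batch_scale_sd: float = 0.25
    subtype_prevalence: float = 0.5  # P(OX+)
    hazard_ratio: float = 2.0
    baseline_hazard: float = 0.12  # events per year for IM+
    censor_rate: float = 0.3
    seed: int = 0

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_sizes)

    @property
    def n_samples(self) -> int:
        return int(sum(self.cohort_sizes))

    def validate(self) -> "SynthConfig":
        if not self.cohort_sizes:
            raise InvalidConfigError("cohort_sizes must be nonempty")
        if any(s <= 0 for s in self.cohort_sizes):
            raise InvalidConfigError("cohort sizes must be positive")
        overlap = set(self.ox_program) & set(self.im_program)
        if overlap:
            raise InvalidConfigError(f"ox/im programs overlap: {sorted(overlap)[:5]}")
        n_prog = len(self.ox_program) + len(self.im_program)
        if n_prog > self.n_shared_genes:
            raise InvalidConfigError("program genes must fit inside the shared gene set")
        if self.n_shared_genes > self.n_genes:
            raise InvalidConfigError("n_shared_genes cannot exceed n_genes")
        if not 0 <= self.delta_p < 1:
            raise InvalidConfigError("delta_p must lie in [0, 1)")
        if not 0 < self.subtype_prevalence < 1:
            raise InvalidConfigError("subtype_prevalence must lie in (0, 1)")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise InvalidConfigError("hazards must be positive")
        if not 0 <= self.censor_rate < 1:
            raise InvalidConfigError("censor_rate must lie in [0, 1)")
        if self.batch_mu_sd < 0 or self.batch_scale_sd < 0:
            raise InvalidConfigError("batch sds must be nonnegative")
        return self

    def gene_names(self) -> list[str]:
        """Shared genes first (programs at the head), then cohort-variable filler."""
        programs = list(self.ox_program) + list(self.im_program)
        n_filler = self.n_genes - len(programs)
        filler = [f"G{i:04d}" for i in range(1, n_filler + 1)]
        return programs + filler


@dataclass
class PlantedTruth:
    """Ground truth of a generated compendium."""

    subtype: dict[str, str]  # sample id -> "OX+" | "IM+"
    cohort: dict[str, str]
    informative_genes: list[str]

    def labels_for(self, samples: list[str]) -> list[str]:
        return [self.subtype[s] for s in samples]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "subtype": self.subtype,
                    "cohort": self.cohort,
                    "informative_genes": self.informative_genes,
                },
                indent=1,
                sort_keys=True,
            )
        )

    @classmethod
    def read(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["subtype"], d["cohort"], d["informative_genes"])


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


def effect_size_for_delta_p(delta_p: float) -> float:
    """Gaussian mean shift giving a ``delta_p`` difference in P(above median)."""
    if delta_p == 0:
        return 0.0
    return float(2.0 * stats.norm.ppf((1.0 + delta_p) / 2.0))


def plant_survival(
    labels: list[str],
    baseline_hazard: float,
    hazard_ratio: float,
    censor_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Draw (time, event) per sample from subtype-specific exponential hazards.

    OX+ samples get hazard ``baseline_hazard * hazard_ratio``.  Censoring is
    an independent exponential clock with rate chosen so that
    P(censored) = censor_rate exactly under the model.
    """
    if baseline_hazard <= 0 or hazard_ratio <= 0:
        raise ValueError("hazards must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    labels_arr = np.asarray(labels)
    n = len(labels_arr)
    rate = np.where(labels_arr == "OX+", baseline_hazard * hazard_ratio, baseline_hazard)
    rng_t = _rng(seed, "survival")
    t_event = rng_t.exponential(1.0 / rate, size=n)
    if censor_rate > 0:
        # For competing exponentials, P(C < T) = rc / (rc + re) per sample.
        c_rate = rate * censor_rate / (1.0 - censor_rate)
        rng_c = _rng(seed, "censoring")
        t_cens = rng_c.exponential(1.0 / c_rate, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    return pd.DataFrame({"os_time_years": time, "os_event": event})


def _clinical_covariates(
    subtype: np.ndarray, cohort_idx: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Mildly subtype-associated demographics and stage, with cohort-level missingness.

    IM+ patients run slightly older and more often female; OX+ tumors skew
    toward higher T/N stage.  A subset of cohorts reports no stage (or no
    demographics at all), as is typical of public series.
    """
    n = len(subtype)
    is_ox = subtype == "OX+"
    age = np.round(rng.normal(np.where(is_ox, 63.1, 64.4), 9.0), 1)
    sex = np.where(rng.random(n) < np.where(is_ox, 0.58, 0.45), "male", "female")

    def _ordinal(categories, probs_ox, probs_im):
        out = np.empty(n, dtype=object)
        for mask, probs in ((is_ox, probs_ox), (~is_ox, probs_im)):
            k = int(mask.sum())
            out[mask] = rng.choice(categories, size=k, p=probs)
        return out

    t_stage = _ordinal(["T1", "T2", "T3"], [0.30, 0.55, 0.15], [0.50, 0.42, 0.08])
    n_stage = _ordinal(["N0", "N1", "N2"], [0.55, 0.28, 0.17], [0.72, 0.19, 0.09])
    m_stage = _ordinal(["M0", "M1"], [0.93, 0.07], [0.96, 0.04])
    df = pd.DataFrame(
        {"age": age, "sex": sex, "t_stage": t_stage, "n_stage": n_stage, "m_stage": m_stage}
    )
    # Cohort-level missingness: every third cohort lacks staging, the first
    # lacks demographics entirely.
    no_stage = np.isin(cohort_idx % 3, [1])
    df.loc[no_stage, ["t_stage", "n_stage", "m_stage"]] = pd.NA
    first = cohort_idx == 0
    df.loc[first, ["age", "sex", "t_stage", "n_stage", "m_stage"]] = pd.NA
    return df


def generate_cohorts(
    config: SynthConfig,
) -> tuple[list[ExpressionMatrix], pd.DataFrame, PlantedTruth]:
    """Generate the compendium: per-cohort expression, clinical table, truth.

    Returns one continuous :class:`ExpressionMatrix` per cohort (cohort ids
    ``C01`` ...), a clinical table covering all samples with prefixed ids
    (``C01_S0001`` ...), and the planted ground truth.  Identical configs
    (including seed) give bit-identical output.
    """
    config.validate()
    genes = config.gene_names()
    n_genes = len(genes)
    shared = genes[: config.n_shared_genes]
    variable = genes[config.n_shared_genes :]
    ox_idx = np.array([genes.index(g) for g in config.ox_program], dtype=int)
    im_idx = np.array([genes.index(g) for g in config.im_program], dtype=int)
    beta = effect_size_for_delta_p(config.delta_p)

    rng_s = _rng(config.seed, "structure")
    # Baseline per-gene means on a log2-expression-like scale.
    mu = rng_s.normal(8.0, 2.0, size=n_genes)
    # Cohort batch parameters: per-(gene, cohort) shift and log-normal scale.
    n_c = config.n_cohorts
    shift = rng_s.normal(0.0, config.batch_mu_sd, size=(n_c, n_genes))
    scale = np.exp(rng_s.normal(0.0, config.batch_scale_sd, size=(n_c, n_genes)))
    # Per-cohort gene inventories: all shared genes plus ~70% of the rest.
    inventories = []
    for c in range(n_c):
        keep = rng_s.random(len(variable)) < 0.7
        inventories.append(shared + [g for g, k in zip(variable, keep) if k])

    rng_e = _rng(config.seed, "expression")
    matrices: list[ExpressionMatrix] = []
    all_samples: list[str] = []
    all_subtypes: list[str] = []
    cohort_of: list[str] = []
    cohort_idx_all: list[int] = []
    for c, size in enumerate(config.cohort_sizes):
        cid = f"C{c + 1:02d}"
        sample_ids = [f"S{i + 1:04d}" for i in range(size)]
        z_ox = (rng_e.random(size) < config.subtype_prevalence).astype(float)
        signal = np.zeros((n_genes, size))
        signal[ox_idx, :] = beta * z_ox[None, :]
        signal[im_idx, :] = beta * (1.0 - z_ox)[None, :]
        eps = rng_e.normal(0.0, 1.0, size=(n_genes, size))
        x = scale[c][:, None] * (mu[:, None] + signal + eps) + shift[c][:, None]
        inv = inventories[c]
        pos = {g: i for i, g in enumerate(genes)}
        rows = [pos[g] for g in inv]
        matrices.append(
            ExpressionMatrix(cohort_id=cid, genes=list(inv), samples=sample_ids, values=x[rows, :])
        )
        all_samples.extend(f"{cid}_{s}" for s in sample_ids)
        all_subtypes.extend("OX+" if z else "IM+" for z in z_ox)
        cohort_of.extend([cid] * size)
        cohort_idx_all.extend([c] * size)

    surv = plant_survival(
        all_subtypes,
        config.baseline_hazard,
        config.hazard_ratio,
        config.censor_rate,
        config.seed,
    )
    rng_cl = _rng(config.seed, "clinical")
    covars = _clinical_covariates(
        np.asarray(all_subtypes), np.asarray(cohort_idx_all), rng_cl
    )
    clinical = pd.DataFrame(
        {
            "sample_id": all_samples,
            "cohort": cohort_of,
            "os_time_years": surv["os_time_years"].to_numpy(),
            "os_event": surv["os_event"].to_numpy(),
        }
    )
    clinical = pd.concat([clinical, covars], axis=1)[CLINICAL_COLUMNS]

    truth = PlantedTruth(
        subtype=dict(zip(all_samples, all_subtypes)),
        cohort=dict(zip(all_samples, cohort_of)),
        informative_genes=list(config.ox_program) + list(config.im_program),
    )
    return matrices, clinical, truth


# ---------------------------------------------------------------------------
# Synthetic gene-set collections aligned with the generator's programs.
# These stand in for curated resources (hallmark pathways, oxidative-stress
# GO sets, immune/stromal signatures, cell-population markers); they are
# synthetic constructs, not the published catalogs.
# ---------------------------------------------------------------------------

def default_gene_sets(config: SynthConfig, seed: int | None = None) -> dict[str, dict[str, list[str]]]:
    """Build the stand-in gene-set collections used throughout the pipeline.

    Returns a dict of GMT-style collections:

    - ``hallmark``: pathway-style sets for enrichment labelling — two
      program-aligned sets plus random decoy sets;
    - ``oxidative``: two oxidative-stress scoring sets (a small 10-gene set
      and a larger ROS-style set), subsets of the OX program;
    - ``signatures``: immune and stromal signatures for microenvironment
      scoring (immune = IM-program based; stromal = a filler-gene set);
    - ``populations``: eight cell-population marker sets.
    """
    rng = np.random.default_rng([(seed if seed is not None else config.seed) % (2**31), 97])
    genes = config.gene_names()
    shared = genes[: config.n_shared_genes]
    filler = [g for g in shared if g not in set(config.ox_program) | set(config.im_program)]
    ox, im = list(config.ox_program), list(config.im_program)

    def _sample(pool, k):
        k = min(k, len(pool))
        return sorted(rng.choice(pool, size=k, replace=False).tolist())

    hallmark = {
        "SYN_OXIDATIVE_PHOSPHORYLATION": ox[: max(5, len(ox) * 3 // 4)],
        "SYN_REACTIVE_OXYGEN_SPECIES": _sample(ox, max(5, len(ox) // 2)),
        "SYN_INFLAMMATORY_RESPONSE": im[: max(5, len(im) * 3 // 4)],
        "SYN_INTERFERON_GAMMA_RESPONSE": _sample(im, max(5, len(im) // 2)),
    }
    for i in range(1, 7):
        hallmark[f"SYN_RANDOM_SET_{i}"] = _sample(filler, 25)

    oxidative = {
        "SYN_POSITIVE_REGULATION_OF_RESPONSE_TO_OXIDATIVE_STRESS": ox[:10],
        "SYN_ROS_PATHWAY": _sample(ox, min(49, len(ox))),
    }
    signatures = {
        "SYN_IMMUNE_SIGNATURE": im[: max(5, len(im) * 3 // 4)],
        "SYN_STROMAL_SIGNATURE": _sample(filler, 30),
    }
    pop_names = [
        "T_cells", "CD8_T_cells", "Cytotoxic_lymphocytes", "B_lineage",
        "NK_cells", "Monocytic_lineage", "Endothelial_cells", "Fibroblasts",
    ]
    populations = {}
    for i, name in enumerate(pop_names):
        # Immune populations draw from the IM program, structural ones from filler.
        pool = im if i < 6 else filler
        populations[name] = _sample(pool, 8)
    return {
        "hallmark": hallmark,
        "oxidative": oxidative,
        "signatures": signatures,
        "populations": populations,
    }


def default_gene_universe(config: SynthConfig, n_extra: int = 50) -> list[str]:
    """Stand-in for a keyword-curated analysis gene list.

    Emulates a curated oxidative-stress/immunotherapy gene catalog: it
    contains both programs in full plus ``n_extra`` shared filler genes —
    curation is topical, not discriminative, so the list also carries genes
    with no subtype signal.  Downstream analyses restrict to this universe,
    as the emulated study restricts to its curated catalog.
    """
    rng = np.random.default_rng([config.seed % (2**31), 131])
    genes = config.gene_names()
    shared = genes[: config.n_shared_genes]
    programs = list(config.ox_program) + list(config.im_program)
    filler = [g for g in shared if g not in set(programs)]
    n_extra = min(n_extra, len(filler))
    extra = sorted(rng.choice(filler, size=n_extra, replace=False).tolist())
    return programs + extra


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_compendium(
    config: SynthConfig, outdir: str | Path
) -> dict[str, object]:
    """Generate and write the full compendium to ``outdir``; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices, clinical, truth = generate_cohorts(config)
    expr_paths = {}
    for m in matrices:
        p = outdir / f"expr_{m.cohort_id}.tsv"
        m.write(p)
        expr_paths[m.cohort_id] = str(p)
    clin_path = outdir / "clinical.tsv"
    clinical.to_csv(clin_path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    truth_path = outdir / "truth.json"
    truth.write(truth_path)
    gmt_paths = {}
    for kind, sets in default_gene_sets(config).items():
        p = outdir / f"{kind}.gmt"
        write_gmt(sets, p)
        gmt_paths[kind] = str(p)
    universe_path = outdir / "gene_universe.txt"
    universe_path.write_text("\n".join(default_gene_universe(config)) + "\n")
    return {
        "expression": expr_paths,
        "clinical": str(clin_path),
        "truth": str(truth_path),
        "gene_sets": gmt_paths,
        "gene_universe": str(universe_path),
    }
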