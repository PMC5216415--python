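"""Synthetic exon-array cohorts with known planted truth.

Emulates the structure of a two-group (tumour subtype vs. normal breast
tissue) exon-array experiment: log2-scale probe intensities grouped by
gene, whole-gene differential expression, exon-proportion imbalances that
conserve total gene expression, survival outcomes driven by selected
features, and a lymphocytic-infiltration confounder.  Every planted effect
is recorded in a truth table so downstream differential, classification
and survival stages can be scored against known answers.

Effect classes per gene:

``null``
    baseline expression in both groups.
``de_only``
    every exon scaled by ``2**de_log2fc`` in the affected group.
``si_only``
    a fraction ``si_delta`` of the gene's total linear expression moved
    onto one target exon in the affected group; the gene total is
    conserved exactly, so the gene is invisible at the whole-gene level.
``both``
    both perturbations combined.

Measurement noise is additive Gaussian on the log2 scale (multiplicative
log-normal on the linear scale), the standard microarray error model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

EFFECT_CLASSES = ("null", "de_only", "si_only", "both")


@dataclass
class GeneModel:
    """A multi-exon gene: one probe per exon with a baseline intensity."""

    gene_id: str
    n_exons: int
    baseline_intensity: np.ndarray  # linear scale, strictly positive

    def __post_init__(self):
        if self.n_exons < 1:
            raise ConfigurationError(f"{self.gene_id}: n_exons must be >= 1")
        self.baseline_intensity = np.asarray(self.baseline_intensity, dtype=float)
        if len(self.baseline_intensity) != self.n_exons:
            raise ConfigurationError(f"{self.gene_id}: baseline length != n_exons")
        if (self.baseline_intensity <= 0).any():
            raise ConfigurationError(f"{self.gene_id}: baselines must be positive")


@dataclass
class PlantedEffect:
    """Ground truth for one gene."""

    gene_id: str
    effect_class: str = "null"
    de_log2fc: float = 0.0
    si_target_exon: int = -1
    si_delta: float = 0.0
    survival_beta: float = 0.0
    survival_driver_level: str = "none"  # {GE, SI, none}
    lymph_module: bool = False

    def __post_init__(self):
        if self.effect_class not in EFFECT_CLASSES:
            raise ConfigurationError(f"unknown effect_class {self.effect_class!r}")
        has_de = self.effect_class in ("de_only", "both")
        has_si = self.effect_class in ("si_only", "both")
        if (self.de_log2fc != 0) != has_de:
            raise ConfigurationError(
                f"{self.gene_id}: de_log2fc inconsistent with {self.effect_class}"
            )
        if (self.si_delta != 0) != has_si:
            raise ConfigurationError(
                f"{self.gene_id}: si_delta inconsistent with {self.effect_class}"
            )
        if not 0 <= self.si_delta < 1:
            raise ConfigurationError(f"{self.gene_id}: si_delta must be in [0, 1)")


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Group sizes default to 40 basal-like tumours vs. 9 normal breast
    tissues; effects are planted in ``affected_group`` relative to the
    rest.  Fractions of the effect classes may sum to at most 1 (the
    remainder of genes is null).
    """

    n_genes: int = 1000
    exon_count_range: tuple[int, int] = (2, 10)
    groups: dict[str, int] = field(default_factory=lambda: {"basal": 40, "NBT": 9})
    affected_group: str = "basal"
    frac_de_only: float = 0.05
    frac_si_only: float = 0.05
    frac_both: float = 0.02
    de_log2fc_range: tuple[float, float] = (0.5, 2.0)
    si_delta_range: tuple[float, float] = (0.1, 0.5)
    noise_sd: float = 0.3
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    n_lymph_genes: int = 0
    lymph_log2fc: float = 1.0
    lymph_fraction_high: float = 0.4
    lymph_log_hr: float = 0.0
    n_survival_ge: int = 0
    n_survival_si: int = 0
    survival_beta: float = math.log(2.0)
    baseline_hazard: float = 0.01  # events per month
    censoring_rate: float = 0.3
    seed: int = 0

    def validate(self):
        lo, hi = self.exon_count_range
        if not (1 <= lo <= hi <= 100):
            raise ConfigurationError("exon_count_range must satisfy 1 <= lo <= hi <= 100")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if any(n <= 0 for n in self.groups.values()):
            raise ConfigurationError("all group sizes must be positive")
        if self.affected_group not in self.groups:
            raise ConfigurationError(f"affected_group {self.affected_group!r} not in groups")
        total = self.frac_de_only + self.frac_si_only + self.frac_both
        if min(self.frac_de_only, self.frac_si_only, self.frac_both) < 0 or total > 1:
            raise ConfigurationError("effect-class fractions must be >= 0 and sum to <= 1")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigurationError("censoring_rate must be in [0, 1)")
        if self.noise_sd < 0 or self.baseline_hazard <= 0:
            raise ConfigurationError("noise_sd must be >= 0 and baseline_hazard > 0")


class Cohort(NamedTuple):
    matrix: pd.DataFrame      # probes x samples, log2
    annotation: pd.DataFrame  # indexed by probe_id
    samples: pd.DataFrame     # indexed by sample_id
    truth: pd.DataFrame       # indexed by gene_id


def generate_gene_models(
    n_genes: int,
    exon_count_range: tuple[int, int],
    seed: int,
    baseline_log2_mean: float = 7.0,
    baseline_log2_sd: float = 1.0,
):
    """Draw gene models and build their probe annotation table.

    Exon counts are uniform on the configured integer range; baseline
    exon intensities are log-normal (Gaussian on log2).  One probe per
    exon; annotation rows are ordered by gene then exon index, with
    synthetic 0-based half-open genomic intervals.
    """
    lo, hi = exon_count_range
    if not (1 <= lo <= hi <= 100):
        raise ConfigurationError("exon_count_range must satisfy 1 <= lo <= hi <= 100")
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    models = []
    rows = []
    cursor = 1000  # running genomic coordinate on a synthetic chromosome
    for i in range(n_genes):
        gene_id = f"G{i + 1:0{width}d}"
        n_exons = int(rng.integers(lo, hi + 1))
        base = np.power(
            2.0, rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_exons)
        )
        models.append(GeneModel(gene_id, n_exons, base))
        for e in range(n_exons):
            start = cursor
            end = start + 150
            rows.append((f"{gene_id}:E{e:02d}", gene_id, e, "chrS", start, end, "+"))
            cursor = end + 100
        cursor += 5000
    annotation = pd.DataFrame(
        rows,
        columns=["probe_id", "gene_id", "exon_index", "chrom", "start", "end", "strand"],
    ).set_index("probe_id")
    return models, annotation


def _plant_effects(models, config: CohortConfig, rng: np.random.Generator):
    """Assign effect classes, survival drivers and the lymphocyte module."""
    n = len(models)
    n_de = round(config.frac_de_only * n)
    n_si = round(config.frac_si_only * n)
    n_both = round(config.frac_both * n)
    multi = [m.gene_id for m in models if m.n_exons >= 2]
    if n_si + n_both + config.n_survival_si > len(multi):
        raise ConfigurationError("not enough multi-exon genes for requested SI effects")
    by_id = {m.gene_id: m for m in models}
    order = list(rng.permutation(multi))
    si_genes = order[:n_si]
    both_genes = order[n_si:n_si + n_both]
    remaining = [m.gene_id for m in models if m.gene_id not in set(si_genes) | set(both_genes)]
    remaining = list(rng.permutation(remaining))
    de_genes = remaining[:n_de]
    pool = remaining[n_de:]

    effects = {m.gene_id: PlantedEffect(m.gene_id) for m in models}

    def _plant_si(gene_id):
        m = by_id[gene_id]
        props = m.baseline_intensity / m.baseline_intensity.sum()
        # target exon must leave room for the proportion shift
        candidates = np.flatnonzero(props < 0.5)
        target = int(rng.choice(candidates if len(candidates) else np.arange(m.n_exons)))
        d_lo, d_hi = config.si_delta_range
        d_hi = min(d_hi, 0.95 - props[target])
        delta = float(rng.uniform(d_lo, max(d_lo, d_hi)))
        return target, delta

    def _draw_lfc():
        lfc = float(rng.uniform(*config.de_log2fc_range))
        return lfc if rng.random() < 0.5 else -lfc

    for g in si_genes:
        t, d = _plant_si(g)
        effects[g] = PlantedEffect(g, "si_only", 0.0, t, d)
    for g in both_genes:
        t, d = _plant_si(g)
        effects[g] = PlantedEffect(g, "both", _draw_lfc(), t, d)
    for g in de_genes:
        effects[g] = PlantedEffect(g, "de_only", _draw_lfc())

    # lymphocyte module and survival drivers live on otherwise-null genes
    # so their signals are not entangled with the group contrast
    null_pool = [g for g in pool if effects[g].effect_class == "null"]
    if config.n_lymph_genes > len(null_pool):
        raise ConfigurationError("not enough null genes for the lymphocyte module")
    for g in null_pool[:config.n_lymph_genes]:
        effects[g].lymph_module = True
    driver_pool = [g for g in null_pool[config.n_lymph_genes:]]
    ge_drivers = driver_pool[:config.n_survival_ge]
    si_driver_pool = [g for g in driver_pool[config.n_survival_ge:] if by_id[g].n_exons >= 2]
    if len(ge_drivers) < config.n_survival_ge or len(si_driver_pool) < config.n_survival_si:
        raise ConfigurationError("not enough null genes for requested survival drivers")
    for g in ge_drivers:
        effects[g].survival_beta = config.survival_beta
        effects[g].survival_driver_level = "GE"
    for g in si_driver_pool[:config.n_survival_si]:
        effects[g].survival_beta = config.survival_beta
        effects[g].survival_driver_level = "SI"
        effects[g].si_target_exon = int(rng.integers(0, by_id[g].n_exons))
    return [effects[m.gene_id] for m in models]


def _truth_frame(effects) -> pd.DataFrame:
    truth = pd.DataFrame(
        [
            (
                e.gene_id, e.effect_class, e.de_log2fc, e.si_target_exon,
                e.si_delta, e.survival_beta, e.survival_driver_level,
                e.lymph_module,
            )
            for e in effects
        ],
        columns=[
            "gene_id", "effect_class", "de_log2fc", "si_target_exon",
            "si_delta", "survival_beta", "survival_driver_level", "lymph_module",
        ],
    ).set_index("gene_id")
    return truth


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort from a :class:`CohortConfig`.

    Returns probe-level log2 expression, probe annotation, a clinical
    sample table (group, receptor status, lymphocytic infiltration and
    survival outcome) and the planted truth table.  Identical configs
    (including seed) produce bit-identical output.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seed_models, seed_fx, seed_noise, seed_surv = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    models, annotation = generate_gene_models(
        config.n_genes, config.exon_count_range, seed_models,
        config.baseline_log2_mean, config.baseline_log2_sd,
    )
    rng = np.random.default_rng(seed_fx)
    effects = _plant_effects(models, config, rng)
    truth = _truth_frame(effects)

    sample_ids, sample_group = [], []
    for group, size in config.groups.items():
        for j in range(size):
            sample_ids.append(f"{group}_{j + 1:03d}")
            sample_group.append(group)
    n_samples = len(sample_ids)
    group_arr = np.asarray(sample_group)
    affected = group_arr == config.affected_group
    lymph_high = rng.random(n_samples) < config.lymph_fraction_high
    lymph_pct = np.where(
        lymph_high, rng.uniform(15, 80, n_samples), rng.uniform(0, 15, n_samples)
    ).round(1)
    lymph_pct = np.where(lymph_high & (lymph_pct < 15), 15.0, lymph_pct)
    lymph_pct = np.where(~lymph_high & (lymph_pct >= 15), 14.9, lymph_pct)

    blocks = []
    for m, e in zip(models, effects):
        base = m.baseline_intensity
        total = base.sum()
        props = base / total
        lin = np.tile((total * props)[:, None], (1, n_samples))
        if e.effect_class in ("si_only", "both") and e.si_delta > 0:
            p2 = props.copy()
            t = e.si_target_exon
            p2[t] = props[t] + e.si_delta
            others = np.arange(m.n_exons) != t
            p2[others] = props[others] * (1 - p2[t]) / (1 - props[t])
            lin[:, affected] = total * p2[:, None]
        if e.effect_class in ("de_only", "both") and e.de_log2fc != 0:
            lin[:, affected] *= 2.0 ** e.de_log2fc
        if e.lymph_module and config.lymph_log2fc != 0:
            lin[:, lymph_high] *= 2.0 ** config.lymph_log2fc
        blocks.append(np.log2(lin))
    values = np.vstack(blocks)
    if config.noise_sd > 0:
        noise_rng = np.random.default_rng(seed_noise)
        values = values + noise_rng.normal(0.0, config.noise_sd, size=values.shape)
    matrix = pd.DataFrame(values, index=annotation.index, columns=sample_ids)

    samples = pd.DataFrame(
        {
            "group": sample_group,
            "er": np.where(affected, "neg", "pos"),
            "pr": np.where(affected, "neg", "pos"),
            "her2": "neg",
            "lymph_pct": lymph_pct,
            "lymph_class": np.where(lymph_pct < 15, "low", "high"),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    features = driver_features(matrix, annotation, truth)
    samples = generate_survival(features, truth, config, seed=seed_surv, samples=samples)
    return Cohort(matrix, annotation, samples, truth)


def driver_features(matrix: pd.DataFrame, annotation: pd.DataFrame, truth: pd.DataFrame):
    """Extract the survival-driver feature values named in the truth table.

    GE drivers are the mean log2 intensity over the gene's probes;
    SI drivers are the splicing index of the planted target exon.
    Returns a samples x features DataFrame (possibly empty).
    """
    from .expression import compute_splicing_index

    cols = {}
    drivers = truth[truth["survival_driver_level"] != "none"]
    if len(drivers) == 0:
        return pd.DataFrame(index=matrix.columns)
    si = None
    for gene, row in drivers.iterrows():
        probes = annotation.index[annotation["gene_id"] == gene]
        if row["survival_driver_level"] == "GE":
            cols[f"GE:{gene}"] = matrix.loc[probes].mean(axis=0)
        else:
            if si is None:
                si = compute_splicing_index(matrix, annotation)
            target = annotation.index[
                (annotation["gene_id"] == gene)
                & (annotation["exon_index"] == int(row["si_target_exon"]))
            ][0]
            cols[f"SI:{gene}:E{int(row['si_target_exon']):02d}"] = si.loc[target]
    return pd.DataFrame(cols, index=matrix.columns)


def _censoring_horizon(hazards: np.ndarray, rate: float) -> float:
    """Horizon H of uniform administrative censoring C ~ U(0, H) such that
    the expected censored fraction under exponential event times matches
    ``rate``; solved by bisection on the closed-form expectation."""

    def frac(h):
        x = hazards * h
        return float(np.mean((1 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1.0
    while frac(hi) > rate:
        hi *= 2
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_survival(
    sample_features: pd.DataFrame,
    truth: pd.DataFrame,
    config: CohortConfig,
    seed: int | None = None,
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw survival times from an exponential proportional-hazards model.

    hazard_i = baseline_hazard * exp(sum_g beta_g * z_gi + lymph effect),
    where z is the cohort-standardized driver feature, so survival_beta is
    a log hazard ratio per SD.  Censoring is administrative, uniform over
    a horizon calibrated to the configured censoring rate.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    drivers = truth[truth["survival_driver_level"] != "none"]
    n = len(sample_features.index)
    log_hr = np.zeros(n)
    for gene, row in drivers.iterrows():
        prefix = f"{row['survival_driver_level']}:{gene}"
        match = [c for c in sample_features.columns if c == prefix or c.startswith(prefix + ":")]
        if not match:
            raise DataError(f"driver feature for gene {gene} missing from sample_features")
        x = sample_features[match[0]].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise DataError(f"driver feature {match[0]} is constant")
        log_hr += row["survival_beta"] * (x - x.mean()) / sd
    if samples is not None and config.lymph_log_hr != 0:
        high = (samples["lymph_class"] == "high").to_numpy()
        log_hr += config.lymph_log_hr * high
    hazards = config.baseline_hazard * np.exp(log_hr)
    times = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        horizon = _censoring_horizon(hazards, config.censoring_rate)
        censor = rng.uniform(0, horizon, size=n)
        event = (times <= censor).astype(int)
        times = np.minimum(times, censor)
    else:
        event = np.ones(n, dtype=int)
    out = samples.copy() if samples is not None else pd.DataFrame(index=sample_features.index)
    out["bcss_time_months"] = np.maximum(times, 1e-6)
    out["bcss_event"] = event
    return out


def write_dataset(matrix, annotation, samples, truth, directory) -> dict[str, Path]:
    """Serialize a cohort to TSV files that round-trip through the readers.

    Writes ``expression.tsv``, ``annotation.tsv``, ``clinical.tsv`` and
    ``truth.tsv`` into ``directory`` and returns the path map.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise DataError("refusing to write an empty cohort")
    if not matrix.index.equals(annotation.index):
        raise DataError("matrix and annotation probe ids differ")
    if not matrix.columns.equals(samples.index):
        raise DataError("matrix columns and sample table ids differ")
    if set(annotation["gene_id"]) != set(truth.index):
        raise DataError("annotation genes and truth table genes differ")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "annotation": directory / "annotation.tsv",
        "clinical": directory / "clinical.tsv",
        "truth": directory / "truth.tsv",
    }
    matrix.to_csv(paths["expression"], sep="\t", index_label="probe_id", float_format="%.17g")
    annotation.to_csv(paths["annotation"], sep="\t", index_label="probe_id")
    samples.to_csv(paths["clinical"], sep="\t", index_label="sample_id")
    truth.to_csv(paths["truth"], sep="\t", index_label="gene_id")
    return paths


def read_dataset(directory) -> Cohort:
    """Load a cohort previously written by :func:`write_dataset`."""
    from .expression import read_expression

    directory = Path(directory)
    matrix, annotation = read_expression(
        directory / "expression.tsv", directory / "annotation.tsv"
    )
    samples = pd.read_csv(directory / "clinical.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(directory / "truth.tsv", sep="\t", index_col=0)
    return Cohort(matrix, annotation, samples, truth)
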