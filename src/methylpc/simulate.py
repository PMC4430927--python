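"""Synthetic matched multi-tissue methylation cohorts with planted factors.

The generator emulates a postmortem cohort design: a set of individuals
each contributing several brain regions (BA10, BA20, BA7) plus whole
blood (WB), assayed on a methylation array and expressed as M-values.
Probe baselines are drawn from a two-mode mixture (low- vs
high-methylated probes), which reproduces the bimodal M-value
distribution responsible for the offset ("zeroth") component in
sample-space PCA.

On top of the baseline, independently controllable factors plant additive
patterns::

    value(probe i, sample s) = baseline_i
        + sum_f loading_{i,f} * score_{s,f} * 1[tissue(s) in affected_tissues(f)]
        + noise

The default factor set mirrors the structure of real matched blood/brain
data: a brain-vs-blood tissue contrast, a neuron-fraction factor (brain
samples only), a granulocyte-fraction factor (blood only), and two age
signatures — ``ageA`` present in every tissue except whole blood and
``ageB`` present in all tissues — planted on disjoint probe sets so that
recovery tests are sharp.  Every planted loading and score is returned as
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel, MethylationMatrix, ProbeAnnotation, SampleMeta

BRAIN_TISSUES = ("BA10", "BA20", "BA7")
RESERVED_FACTOR_NAMES = {"sample_id", "individual_id", "tissue", "age", "chip", "chip_position"}


@dataclass
class FactorSpec:
    """One planted factor.

    effect_size is in M-units per unit of the (standardized) factor score;
    affected_probe_fraction is the fraction of probes carrying a nonzero
    loading; context_bias optionally enriches the factor's probes for an
    annotation category, e.g. {"density_class": "HC", "enrichment": 3.0}
    makes HC probes 3x as likely to be chosen.
    """

    name: str
    affected_tissues: tuple
    affected_probe_fraction: float = 0.05
    effect_size: float = 1.0
    context_bias: dict | None = None
    orthogonal_to: str | None = None


@dataclass
class SimulationConfig:
    n_individuals: int = 17
    tissues: tuple = ("BA10", "BA20", "BA7", "WB")
    n_probes: int = 20000
    age_range: tuple = (15.0, 87.0)
    high_fraction: float = 0.5          # fraction of high-methylated probes
    m_modes: tuple = (-2.0, 2.0)        # low / high baseline M-values
    baseline_jitter: float = 0.3        # per-probe SD around its mode
    factors: list = field(default_factory=list)
    noise_sd: float = 0.2
    missing_samples: tuple = ()          # (individual_index, tissue) pairs
    neuron_beta: tuple = (8.0, 4.0)     # Beta params for neuron fraction
    granulocyte_beta: tuple = (12.0, 6.0)
    n_genes: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.n_probes < 100:
            raise ValueError("n_probes must be >= 100")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.high_fraction <= 1:
            raise ValueError("high_fraction must be in [0,1]")
        names = [f.name for f in self.factors]
        clash = set(names) & RESERVED_FACTOR_NAMES
        if clash:
            raise ValueError(f"factor names collide with metadata columns: {sorted(clash)}")
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-factor probe loadings and per-sample scores."""

    loadings: pd.DataFrame          # probes x factors, M-units
    scores: pd.DataFrame            # samples x factors (incl. age, fractions)
    probe_context: pd.DataFrame     # annotation used for the probes
    baseline: np.ndarray            # per-probe baseline M-values
    config: SimulationConfig


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-scale defaults: 17 individuals x 4 tissues (one BA20 and one
    WB held out, 66 samples), 20,000 probes, five planted factors."""
    factors = [
        FactorSpec("brain_vs_blood", BRAIN_TISSUES + ("WB",), 0.10, 2.0,
                   context_bias={"density_class": "LC", "enrichment": 3.0}),
        FactorSpec("neuron", BRAIN_TISSUES, 0.05, 1.5,
                   context_bias={"is_CH": True, "enrichment": 3.0}),
        FactorSpec("granulo", ("WB",), 0.05, 1.5),
        FactorSpec("ageA", BRAIN_TISSUES, 0.05, 0.8,
                   context_bias={"density_class": "HC", "enrichment": 3.0},
                   orthogonal_to="ageB"),
        FactorSpec("ageB", BRAIN_TISSUES + ("WB",), 0.05, 0.6,
                   context_bias={"density_class": "HC", "enrichment": 2.0}),
    ]
    cfg = SimulationConfig(
        factors=factors,
        missing_samples=((15, "BA20"), (16, "WB")),
        seed=seed,
        **overrides,
    )
    return cfg


# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _decorrelate_from(values: np.ndarray, covariate: np.ndarray,
                      lo: float = 0.01, hi: float = 0.99) -> np.ndarray:
    """Remove the linear covariate component from ``values``, preserving
    their mean and SD; result clipped into (lo, hi) for fraction-valued
    phenotypes."""
    if len(values) < 3 or covariate.std() == 0:
        return values
    mu, sd = values.mean(), values.std()
    z = _standardize(values)
    c = _standardize(covariate)
    resid = z - (z @ c) / (c @ c) * c
    rsd = resid.std()
    if rsd == 0:
        return values
    return np.clip(mu + sd * resid / rsd, lo, hi)


def _factor_probe_sets(cfg: SimulationConfig, annotation: pd.DataFrame, rng) -> dict:
    """Choose each factor's probe set; age factors get disjoint sets."""
    n = cfg.n_probes
    sets = {}
    taken_by_age = np.zeros(n, dtype=bool)
    for f in cfg.factors:
        k = int(round(f.affected_probe_fraction * n))
        weights = np.ones(n)
        if f.context_bias:
            bias = dict(f.context_bias)
            enr = float(bias.pop("enrichment", 2.0))
            for col, val in bias.items():
                weights = np.where(annotation[col].to_numpy() == val, enr, weights)
        if f.name.startswith("age"):
            weights = weights * (~taken_by_age)
        weights = weights / weights.sum()
        chosen = rng.choice(n, size=k, replace=False, p=weights)
        mask = np.zeros(n, dtype=bool)
        mask[chosen] = True
        if f.name.startswith("age"):
            taken_by_age |= mask
        sets[f.name] = mask
    return sets


def _make_annotation(cfg: SimulationConfig, rng) -> pd.DataFrame:
    n = cfg.n_probes
    probe_ids = [f"cg{i:07d}" for i in range(n)]
    # chromosome 1..5 plus a small X/Y contingent so filtering is exercised
    chrom = rng.choice(["1", "2", "3", "4", "5"], size=n)
    density = rng.choice(DENSITY_P[0], size=n, p=DENSITY_P[1])
    region = rng.choice(REGION_P[0], size=n, p=REGION_P[1])
    is_ch = rng.random(n) < 0.02
    position = rng.integers(1, 5_000_000, size=n)
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chrom,
            "position": position,
            "density_class": density,
            "region_class": region,
            "is_CH": is_ch,
        }
    )


DENSITY_P = (["HC", "IC", "ICshore", "LC"], [0.30, 0.15, 0.15, 0.40])
REGION_P = (["intron", "exon", "intergenic"], [0.40, 0.25, 0.35])


def _make_genes(cfg: SimulationConfig, annotation: pd.DataFrame, rng) -> list:
    """Gene models sharing chromosomes with the probes; spacing mixes lone
    and non-lone genes."""
    genes = []
    chroms = ["1", "2", "3", "4", "5"]
    per_chrom = max(1, cfg.n_genes // len(chroms))
    gid = 0
    for c in chroms:
        pos = 10_000
        for _ in range(per_chrom):
            gap = int(rng.integers(2_000, 40_000))
            pos += gap
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{gid:05d}", c, strand, pos))
            gid += 1
    return genes


def simulate_cohort(config: SimulationConfig):
    """Generate (matrix, meta, annotation, genes, truth) for a matched cohort.

    Same config and seed give bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    annotation_df = _make_annotation(cfg, rng)
    genes = _make_genes(cfg, annotation_df, rng)

    # individuals and their sample grid; cell-composition phenotypes are
    # decorrelated from age across individuals (independent phenotypes,
    # realised exactly in the cohort so that planted factors are
    # identifiable rather than mixed through chance correlations)
    ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=cfg.n_individuals)
    neuron = _decorrelate_from(rng.beta(*cfg.neuron_beta, size=cfg.n_individuals), ages)
    granulo = _decorrelate_from(rng.beta(*cfg.granulocyte_beta, size=cfg.n_individuals), ages)
    missing = set((int(i), t) for i, t in cfg.missing_samples)

    rows = []
    for i in range(cfg.n_individuals):
        for t in cfg.tissues:
            if (i, t) in missing:
                continue
            rows.append((f"ind{i:02d}_{t}", f"ind{i:02d}", t, ages[i], neuron[i], granulo[i]))
    meta_df = pd.DataFrame(
        rows, columns=["sample_id", "individual_id", "tissue", "age",
                       "neuron_fraction", "granulocyte_fraction"]
    )
    n_samples = len(meta_df)
    meta_df["chip"] = [f"chip{j % 3}" for j in range(n_samples)]
    meta_df["chip_position"] = [f"pos{j % 6}" for j in range(n_samples)]

    # per-sample factor scores
    age_z = _standardize(meta_df["age"].to_numpy())
    neuron_z = _standardize(meta_df["neuron_fraction"].to_numpy())
    granulo_z = _standardize(meta_df["granulocyte_fraction"].to_numpy())
    is_brain = meta_df["tissue"].isin(BRAIN_TISSUES).to_numpy()
    tissue_score = np.where(is_brain, 1.0, -1.0)

    score_map = {
        "brain_vs_blood": tissue_score,
        "neuron": neuron_z,
        "granulo": granulo_z,
        "ageA": age_z,
        "ageB": age_z,
    }

    probe_sets = _factor_probe_sets(cfg, annotation_df, rng)

    # baseline: bimodal probe means
    n = cfg.n_probes
    high = rng.random(n) < cfg.high_fraction
    baseline = np.where(high, cfg.m_modes[1], cfg.m_modes[0]) + rng.normal(
        0.0, cfg.baseline_jitter, size=n
    )

    loadings = {}
    X = np.tile(baseline[:, None], (1, n_samples))
    scores_out = {"age": meta_df["age"].to_numpy(),
                  "neuron_fraction": meta_df["neuron_fraction"].to_numpy(),
                  "granulocyte_fraction": meta_df["granulocyte_fraction"].to_numpy(),
                  "is_brain": is_brain.astype(float)}
    effs = {}
    for f in cfg.factors:
        mask = probe_sets[f.name]
        load = np.zeros(n)
        # loadings: random signs, magnitude ~ |N(effect, effect/3)|
        signs = np.where(rng.random(mask.sum()) < 0.5, -1.0, 1.0)
        mag = np.abs(rng.normal(f.effect_size, f.effect_size / 3.0, size=mask.sum()))
        load[mask] = signs * mag
        loadings[f.name] = load
        score = score_map.get(f.name)
        if score is None:
            score = rng.normal(size=n_samples)
        in_tissue = meta_df["tissue"].isin(f.affected_tissues).to_numpy()
        effs[f.name] = score * in_tissue
    # orthogonal contrasts: a factor declared orthogonal_to another keeps
    # only the part of its sample pattern not explained by that factor
    # (e.g. brain-specific excess aging beyond the shared age signature)
    for f in cfg.factors:
        if f.orthogonal_to:
            if f.orthogonal_to not in effs:
                raise ValueError(f"{f.name}: unknown orthogonal_to {f.orthogonal_to!r}")
            ref = effs[f.orthogonal_to]
            denom = float(ref @ ref)
            if denom > 0:
                effs[f.name] = effs[f.name] - (effs[f.name] @ ref) / denom * ref
    for f in cfg.factors:
        X += np.outer(loadings[f.name], effs[f.name])
        scores_out[f"{f.name}_score"] = effs[f.name]
    if cfg.noise_sd > 0:
        X += rng.normal(0.0, cfg.noise_sd, size=X.shape)

    matrix = MethylationMatrix(list(annotation_df["probe_id"]),
                               list(meta_df["sample_id"]), X)
    truth = SyntheticTruth(
        loadings=pd.DataFrame(loadings, index=annotation_df["probe_id"]),
        scores=pd.DataFrame(scores_out, index=meta_df["sample_id"]),
        probe_context=annotation_df.copy(),
        baseline=baseline.copy(),
        config=cfg,
    )
    return matrix, SampleMeta(meta_df), ProbeAnnotation(annotation_df), genes, truth


def simulate_validation_cohort(
    config: SimulationConfig,
    truth: SyntheticTruth,
    tissue: str,
    n_individuals: int,
    seed: int,
    age_range: tuple | None = None,
):
    """Independent cohort of one tissue re-using the reference loadings.

    New individuals, new ages, identical probes and factor loadings; used
    to test whether patterns discovered in the reference transfer.  Returns
    (matrix, meta); with ``n_individuals=0`` an empty frame pair is
    returned.
    """
    cfg = config
    if tissue not in cfg.tissues:
        raise ValueError(f"unknown tissue {tissue!r}; config has {cfg.tissues}")
    rng = np.random.default_rng(seed)
    lo, hi = age_range if age_range is not None else cfg.age_range
    ages = rng.uniform(lo, hi, size=n_individuals)
    neuron = rng.beta(*cfg.neuron_beta, size=n_individuals)
    granulo = rng.beta(*cfg.granulocyte_beta, size=n_individuals)
    meta_df = pd.DataFrame(
        {
            "sample_id": [f"val{i:03d}_{tissue}" for i in range(n_individuals)],
            "individual_id": [f"val{i:03d}" for i in range(n_individuals)],
            "tissue": tissue,
            "age": ages,
            "neuron_fraction": neuron,
            "granulocyte_fraction": granulo,
        }
    )
    if n_individuals == 0:
        return None, SampleMeta(meta_df)

    probe_ids = list(truth.loadings.index)
    n = len(probe_ids)
    baseline_ref = truth.baseline

    age_z = _standardize(ages)
    neuron_z = _standardize(neuron)
    granulo_z = _standardize(granulo)
    score_map = {
        "brain_vs_blood": np.full(n_individuals, 1.0 if tissue in BRAIN_TISSUES else -1.0),
        "neuron": neuron_z,
        "granulo": granulo_z,
        "ageA": age_z,
        "ageB": age_z,
    }
    X = np.tile(baseline_ref[:, None], (1, n_individuals))
    for f in cfg.factors:
        if tissue not in f.affected_tissues:
            continue
        load = truth.loadings[f.name].to_numpy()
        score = score_map.get(f.name)
        if score is None:
            score = rng.normal(size=n_individuals)
        X += np.outer(load, score)
    if cfg.noise_sd > 0:
        X += rng.normal(0.0, cfg.noise_sd, size=X.shape)
    matrix = MethylationMatrix(probe_ids, list(meta_df["sample_id"]), X)
    return matrix, SampleMeta(meta_df)
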