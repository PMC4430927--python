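"""Correlating PC patterns with phenotypes, batch scans, variance accounting
and the subsampling power analysis.

All correlations are Pearson with two-sided p-values from the t transform
with n-2 degrees of freedom.  The power analysis mirrors a study-design
question: given a cohort with an age-correlated methylation pattern, how
often does a PCA screen (every PC tested against age at a per-PC alpha)
detect it at a given sample size?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MethylationMatrix, SampleMeta
from .pca import MethylationPCAResults, fit_pca


class AssociationError(ValueError):
    pass


@dataclass
class AssociationResult:
    pc_index: int
    trait: str
    subset: str
    r: float
    p_value: float
    n: int


@dataclass
class PowerCurve:
    n_grid: list
    reps: int
    detection_fraction: list
    alpha: float
    seed: int
    n_pcs_tested: list | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n_grid, "detection_fraction": self.detection_fraction})


def _pearson(x: np.ndarray, y: np.ndarray):
    if len(x) < 3:
        raise AssociationError(f"need >= 3 samples, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AssociationError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_vector_with_trait(values, trait, subset=None, trait_name="trait",
                                subset_name="all", pc_index=0) -> AssociationResult:
    """Pearson correlation of a per-sample vector with a phenotype.

    ``subset`` is an optional boolean mask applied to both vectors.
    """
    values = np.asarray(values, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if subset is not None:
        mask = np.asarray(subset, dtype=bool)
        values, trait = values[mask], trait[mask]
    r, p = _pearson(values, trait)
    return AssociationResult(pc_index, trait_name, subset_name, r, p, len(values))


def associate_all_pcs(result: MethylationPCAResults, meta: SampleMeta,
                      traits, subsets=None) -> pd.DataFrame:
    """Correlate every PC with every trait within every sample subset.

    ``traits`` is a list of metadata column names (numeric, or categorical
    with exactly two levels which are coded 0/1).  ``subsets`` maps subset
    name -> boolean mask over samples (in matrix order); default is the
    single subset "all".  Returns a table with one row per
    (PC, trait, subset), sortable by |r|.
    """
    meta = meta.aligned_to(result.sample_ids)
    if subsets is None:
        subsets = {"all": np.ones(len(result.sample_ids), dtype=bool)}
    rows = []
    for trait in traits:
        raw = meta.table[trait]
        if raw.dtype == object or str(raw.dtype) == "category":
            levels = sorted(raw.unique())
            if len(levels) != 2:
                raise AssociationError(
                    f"categorical trait {trait!r} must have 2 levels, has {len(levels)}"
                )
            vec = (raw == levels[1]).to_numpy(float)
        else:
            vec = raw.to_numpy(float)
        for sub_name, mask in subsets.items():
            mask = np.asarray(mask, dtype=bool)
            for k in range(1, result.n_components + 1):
                try:
                    res = correlate_vector_with_trait(
                        result.scores(k), vec, mask, trait, sub_name, k
                    )
                except AssociationError:
                    continue
                rows.append((k, trait, sub_name, res.r, res.p_value, res.n))
    table = pd.DataFrame(rows, columns=["pc", "trait", "subset", "r", "p_value", "n"])
    return table.assign(abs_r=table["r"].abs()).sort_values(
        "abs_r", ascending=False).drop(columns="abs_r").reset_index(drop=True)


def batch_effect_scan(result: MethylationPCAResults, meta: SampleMeta,
                      batch_vars=("chip", "chip_position"), alpha: float = 0.01,
                      top_k: int = 5) -> pd.DataFrame:
    """KS scan for batch structure in the top PCs.

    For every level of every batch variable and each of the top ``top_k``
    PCs, a two-sample KS test compares that level's PC scores against all
    other samples'.  Significance is Bonferroni-adjusted over all tests
    performed (#levels x top_k).
    """
    meta = meta.aligned_to(result.sample_ids)
    top_k = min(top_k, result.n_components)
    levels = []
    for var in batch_vars:
        for level in sorted(meta.table[var].unique()):
            mask = (meta.table[var] == level).to_numpy()
            if mask.sum() < 2 or (~mask).sum() < 2:
                warnings.warn(f"batch level {var}={level} has <2 samples; skipped")
                continue
            levels.append((var, level, mask))
    n_tests = len(levels) * top_k
    rows = []
    for var, level, mask in levels:
        for k in range(1, top_k + 1):
            scores = result.scores(k)
            ks = stats.ks_2samp(scores[mask], scores[~mask])
            p_adj = min(1.0, ks.pvalue * n_tests)
            rows.append((var, str(level), k, float(ks.statistic), float(ks.pvalue),
                         p_adj, p_adj < alpha))
    return pd.DataFrame(rows, columns=["batch_var", "level", "pc", "ks_statistic",
                                       "p_value", "p_bonferroni", "significant"])


def variance_by_tissue(matrix: MethylationMatrix, meta: SampleMeta,
                       deflate_result: MethylationPCAResults | None = None,
                       deflate_pcs=None):
    """Per-tissue probe-variance distributions and their KS separations.

    Returns ``(variances, ks_table, percent_share)`` where ``variances``
    maps tissue -> per-probe variance vector (within-tissue, ddof=1),
    ``ks_table`` holds the KS statistic for every tissue pair, and
    ``percent_share`` maps tissue -> its summed probe variance as percent
    of the grand total.  If ``deflate_pcs`` is given (with the fitted
    ``deflate_result``), those components are subtracted from the data
    first, e.g. to remove cell-composition variance.
    """
    if deflate_pcs:
        if deflate_result is None:
            raise AssociationError("deflate_pcs requires deflate_result")
        matrix = deflate_result.deflate(deflate_pcs)
    meta = meta.aligned_to(matrix.sample_ids)
    tissue = meta.table["tissue"].to_numpy()
    variances = {}
    for t in pd.unique(tissue):
        cols = tissue == t
        if cols.sum() < 2:
            warnings.warn(f"tissue {t} has <2 samples; excluded")
            continue
        variances[t] = matrix.values[:, cols].var(axis=1, ddof=1)
    if not variances:
        raise AssociationError("no tissue with >= 2 samples")
    rows = []
    names = list(variances)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ks = stats.ks_2samp(variances[a], variances[b])
            rows.append((a, b, float(ks.statistic), float(ks.pvalue)))
    ks_table = pd.DataFrame(rows, columns=["tissue_a", "tissue_b", "ks_statistic", "p_value"])
    totals = {t: float(v.sum()) for t, v in variances.items()}
    grand = sum(totals.values())
    percent = {t: 100.0 * s / grand for t, s in totals.items()}
    return variances, ks_table, percent


def deflate_composition_pcs(result: MethylationPCAResults, meta: SampleMeta,
                            proportion_cols, r_threshold: float = 0.8):
    """Identify PCs tracking supplied cell proportions (|r| > threshold)
    and return the deflated matrix together with the removed PC indices."""
    meta = meta.aligned_to(result.sample_ids)
    to_remove = []
    for col in proportion_cols:
        vec = meta.table[col].to_numpy(float)
        if np.std(vec) == 0:
            continue
        for k in range(1, result.n_components + 1):
            r, _ = _pearson(result.scores(k), vec)
            if abs(r) > r_threshold and k not in to_remove:
                to_remove.append(k)
    if to_remove:
        return result.deflate(sorted(to_remove)), sorted(to_remove)
    return result.model.matrix, []


def power_subsampling(matrix: MethylationMatrix, meta: SampleMeta, trait: str,
                      n_grid, reps: int, alpha: float = 0.01,
                      deflate_composition: bool = False,
                      proportion_cols=("granulocyte_fraction",),
                      seed: int = 0, bonferroni: bool = False) -> PowerCurve:
    """Detection rate of a trait-correlated PC at reduced sample sizes.

    For each n in ``n_grid``: repeat ``reps`` times {draw n individuals
    without replacement, fit the PCA on their samples, correlate every PC
    with the trait, count success if any per-PC p < alpha}.  With
    ``bonferroni=True`` the per-PC threshold becomes alpha / #PCs.  With
    ``deflate_composition=True``, PCs correlating with the supplied cell
    proportions at |r| > 0.8 are deflated before subsampling.
    """
    meta = meta.aligned_to(matrix.sample_ids)
    if deflate_composition:
        full = fit_pca(matrix)
        matrix, _ = deflate_composition_pcs(full, meta, proportion_cols)
    individuals = meta.table["individual_id"].unique()
    n_ind = len(individuals)
    rng = np.random.default_rng(seed)
    fractions, pcs_tested = [], []
    for n in n_grid:
        if n < 4:
            raise AssociationError(f"subsample size {n} < 4")
        if n > n_ind:
            raise AssociationError(f"subsample size {n} > {n_ind} individuals")
        hits = 0
        k_used = 0
        for _ in range(reps):
            chosen = set(rng.choice(individuals, size=n, replace=False))
            mask = meta.table["individual_id"].isin(chosen).to_numpy()
            ids = [s for s, m in zip(matrix.sample_ids, mask) if m]
            sub = matrix.subset_samples(ids)
            sub_meta = meta.aligned_to(ids)
            res = fit_pca(MethylationMatrix(sub.probe_ids, sub.sample_ids,
                                            sub.values))
            vec = sub_meta.table[trait].to_numpy(float)
            if np.std(vec) == 0:
                continue
            k_used = res.n_components
            thresh = alpha / res.n_components if bonferroni else alpha
            found = False
            for k in range(1, res.n_components + 1):
                _, p = _pearson(res.scores(k), vec)
                if p < thresh:
                    found = True
                    break
            hits += found
        fractions.append(hits / reps)
        pcs_tested.append(k_used)
    return PowerCurve(list(n_grid), reps, fractions, alpha, seed, pcs_tested)


def null_screen_rate(n_samples: int, n_pcs: int, alpha: float = 0.01,
                     reps: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo family-wise rate of the per-PC screen under the null.

    Independent oracle for the power analysis' false-positive rate: draws
    a random orthonormal score matrix (as PCA of spherical noise would
    produce) and a random trait, and reports how often any of the
    ``n_pcs`` score vectors correlates with the trait at per-PC ``alpha``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        g = rng.normal(size=(n_samples, n_pcs))
        q, _ = np.linalg.qr(g)
        trait = rng.normal(size=n_samples)
        found = False
        for k in range(n_pcs):
            _, p = _pearson(q[:, k], trait)
            if p < alpha:
                found = True
                break
        hits += found
    return hits / reps


def recover_planted_factors(result: MethylationPCAResults, meta: SampleMeta,
                            brain_tissues=("BA10", "BA20", "BA7"),
                            blood_tissue="WB", max_pc: int | None = None) -> pd.DataFrame:
    """Map each canonical cohort factor to its best-correlated PC.

    Evaluates, each within its natural sample subset: the brain-vs-blood
    contrast (all samples), neuron fraction (brain samples), granulocyte
    fraction (blood samples), age in brain (the signature absent from
    blood is found among brain samples) and age in blood (the pan-tissue
    signature is the one detectable in blood).  Returns one row per
    factor with the argmax-|r| PC; a recovery succeeds when the five
    factors land on five distinct PCs.
    """
    meta = meta.aligned_to(result.sample_ids)
    is_brain = meta.table["tissue"].isin(brain_tissues).to_numpy()
    is_blood = (meta.table["tissue"] == blood_tissue).to_numpy()
    age = meta.table["age"].to_numpy(float)
    n_pc = max_pc or min(10, result.n_components)
    from scipy.optimize import linear_sum_assignment

    def corr(k, vec, mask):
        scores = result.scores(k)
        v, t = (scores[mask], vec[mask]) if mask is not None else (scores, vec)
        if np.std(t) == 0 or np.std(v) == 0:
            return 0.0, 1.0, len(t)
        r, p = _pearson(v, t)
        return r, p, len(t)

    # simple factors score by |r| in their natural subset
    specs = [("brain_vs_blood", is_brain.astype(float), None)]
    if "neuron_fraction" in meta.table.columns:
        specs.append(("neuron", meta.table["neuron_fraction"].to_numpy(float), is_brain))
    if "granulocyte_fraction" in meta.table.columns:
        specs.append(("granulo", meta.table["granulocyte_fraction"].to_numpy(float), is_blood))

    names, score_rows, report = [], [], {}
    for name, vec, mask in specs:
        row = []
        for k in range(1, n_pc + 1):
            r, p, n = corr(k, vec, mask)
            row.append(abs(r))
            report[(name, k)] = (r, p, n)
        names.append(name)
        score_rows.append(row)

    # the two age signatures share the trait, so |r| alone cannot tell
    # them apart: the pan-tissue signature is SIGN-CONCORDANT between
    # brain and blood, while the brain-specific contrast is not.  Score
    # ageB by concordant strength min(|r_brain|,|r_blood|), and ageA by
    # the brain age strength not explained by a concordant signature.
    row_a, row_b = [], []
    for k in range(1, n_pc + 1):
        r_br, p_br, n_br = corr(k, age, is_brain)
        r_bl, p_bl, n_bl = corr(k, age, is_blood)
        concordant = min(abs(r_br), abs(r_bl)) if r_br * r_bl > 0 else 0.0
        row_b.append(concordant)
        row_a.append(max(abs(r_br) - concordant, 0.0))
        report[("ageA", k)] = (r_br, p_br, n_br)
        report[("ageB", k)] = (r_bl, p_bl, n_bl)
    names += ["ageA", "ageB"]
    score_rows += [row_a, row_b]

    # one-to-one matching maximizing total score: subset-restricted
    # correlations are scale-invariant, so a weak PC's near-zero sample
    # block can echo a stronger factor; a globally optimal assignment
    # (rather than independent argmaxes) keeps each factor on its own PC
    S = np.array(score_rows)
    rows_idx, cols_idx = linear_sum_assignment(-S)
    rows = []
    for i, j in zip(rows_idx, cols_idx):
        r, p, n = report[(names[i], j + 1)]
        rows.append((names[i], j + 1, r, abs(r), p, n))
    return pd.DataFrame(rows, columns=["factor", "pc", "r", "abs_r", "p_value", "n"])
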