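"""Brain-blood concordance of inter-individual PC variation.

Tissue- and composition-dominated PCs (typically the first few) say
nothing about whether an individual's methylation pattern is shared
across tissues, so the analysis runs on the PCs after a cutoff.  For each
such PC, the individual's brain-region entries are averaged into one
brain value, and the PC is called concordant when (a) blood and brain
carry variation of comparable magnitude,

    |sigma2_blood - sigma2_brain| < (sigma2_blood + sigma2_brain) / 2,

and (b) the brain-averaged and blood entries correlate across individuals
at p below a chosen alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleMeta
from .pca import MethylationPCAResults
from .simulate import BRAIN_TISSUES


class ConcordanceError(ValueError):
    pass


@dataclass
class ConcordanceRecord:
    pc_index: int
    sigma2_blood: float
    sigma2_brain: float
    comparable: bool
    r: float
    p_value: float
    selected: bool
    variance_share: float


def average_brain_entries(pc_values, meta: SampleMeta, sample_ids=None,
                          brain_tissues=BRAIN_TISSUES, blood_tissue="WB"):
    """Collapse each individual's brain-region PC entries to their mean.

    Returns ``(individual_ids, brain_means, blood_values)`` over the
    individuals having at least one brain sample and exactly one blood
    sample; others are dropped with a warning.
    """
    pc_values = np.asarray(pc_values, dtype=float)
    table = meta.table
    if sample_ids is not None:
        table = meta.aligned_to(sample_ids).table
    if len(table) != len(pc_values):
        raise ConcordanceError("PC vector and metadata length mismatch")
    inds, brains, bloods = [], [], []
    dropped = 0
    for ind, grp in table.assign(_pc=pc_values).groupby("individual_id", sort=True):
        brain_vals = grp.loc[grp["tissue"].isin(brain_tissues), "_pc"]
        blood_vals = grp.loc[grp["tissue"] == blood_tissue, "_pc"]
        if len(brain_vals) < 1 or len(blood_vals) != 1:
            dropped += 1
            continue
        inds.append(ind)
        brains.append(float(brain_vals.mean()))
        bloods.append(float(blood_vals.iloc[0]))
    if dropped:
        warnings.warn(f"{dropped} individuals lacked a brain or blood sample; dropped")
    if not inds:
        raise ConcordanceError("no individual has both brain and blood samples")
    return inds, np.array(brains), np.array(bloods)


def variance_comparable(sigma2_blood: float, sigma2_brain: float) -> bool:
    """Are the two variances of comparable magnitude?

    True iff |s_blood - s_brain| < (s_blood + s_brain)/2.  Both zero is
    degenerate and returns False with a warning.
    """
    if sigma2_blood < 0 or sigma2_brain < 0:
        raise ConcordanceError("variances must be non-negative")
    if sigma2_blood == 0 and sigma2_brain == 0:
        warnings.warn("both variances are zero; not comparable")
        return False
    return abs(sigma2_blood - sigma2_brain) < 0.5 * (sigma2_blood + sigma2_brain)


def select_concordant_pcs(result: MethylationPCAResults, meta: SampleMeta,
                          start_after_pc: int = 3, alpha: float = 0.01,
                          brain_tissues=BRAIN_TISSUES, blood_tissue="WB",
                          method: str = "pearson"):
    """Concordance screen over the PCs after ``start_after_pc``.

    Returns ``(records_table, summary)``; the summary reports the
    eigenvalue fraction of the selected PCs among all post-cutoff PCs and
    the eigenvalue-weighted split of selected PCs between positive and
    negative brain-blood correlation.  ``method`` may be "spearman" for a
    rank-based alternative; the default follows ordinary product-moment
    correlation.
    """
    if result.n_components <= start_after_pc:
        raise ConcordanceError(
            f"no PCs beyond cutoff {start_after_pc} (have {result.n_components})"
        )
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    records = []
    for k in range(start_after_pc + 1, result.n_components + 1):
        pc = result.scores(k)
        _, brain, blood = average_brain_entries(
            pc, meta, result.sample_ids, brain_tissues, blood_tissue
        )
        s_blood = float(np.var(blood, ddof=1))
        s_brain = float(np.var(brain, ddof=1))
        comparable = variance_comparable(s_blood, s_brain)
        if np.std(brain) == 0 or np.std(blood) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = corr(brain, blood)
        selected = bool(comparable and p < alpha)
        records.append(ConcordanceRecord(k, s_blood, s_brain, comparable,
                                         float(r), float(p), selected, np.nan))
    post_eigs = result.eigenvalues[start_after_pc:]
    total = float(post_eigs.sum())
    for rec, eig in zip(records, post_eigs):
        rec.variance_share = float(eig / total) if total > 0 else 0.0
    sel = [(rec, eig) for rec, eig in zip(records, post_eigs) if rec.selected]
    sel_total = sum(e for _, e in sel)
    pos = sum(e for rec, e in sel if rec.r > 0)
    neg = sum(e for rec, e in sel if rec.r < 0)
    summary = {
        "n_selected": len(sel),
        "selected_variance_fraction": float(sel_total / total) if total > 0 else 0.0,
        "positive_share": float(pos / sel_total) if sel_total > 0 else 0.0,
        "negative_share": float(neg / sel_total) if sel_total > 0 else 0.0,
    }
    table = pd.DataFrame([vars(rec) for rec in records])
    return table, summary
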