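"""Transfer of PCs to independent cohorts via probe-projection votes.

A fitted reference PCA assigns each probe a projection (a signed "vote")
on each PC.  Given a new cohort matrix Y over (a subset of) the same
probes, the reference pattern is reconstructed in the new samples as

    V~ = norm(Yc^T P)

where P holds the reference projections and Yc is the target matrix after
the same preprocessing the reference received: per-sample (column) mean
subtraction followed by removal of the per-probe offset, both computed on
the target itself.  Column normalisation to unit length removes the
arbitrary positive scale.  On the reference data itself this identity
returns the original components exactly (X'^T X' V = (N-1) V Lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MethylationMatrix
from .association import AssociationResult, _pearson


class ReconstructionError(ValueError):
    pass


@dataclass
class ReconstructionInput:
    projections: np.ndarray      # matched probes x selected PCs
    target: np.ndarray           # matched probes x new samples, raw M-values
    probe_ids: list
    sample_ids: list
    coverage: float
    center_target: bool = True


def match_probes(reference_probe_ids, target_probe_ids, floor: int = 100):
    """Intersect probe lists, preserving reference order.

    Returns ``(common_ids, ref_idx, target_idx, coverage)`` with coverage
    = |common| / |reference|; errors if fewer than ``floor`` probes match.
    """
    if not len(reference_probe_ids) or not len(target_probe_ids):
        raise ReconstructionError("empty probe list")
    target_pos = {p: j for j, p in enumerate(target_probe_ids)}
    common, ref_idx, tgt_idx = [], [], []
    for i, p in enumerate(reference_probe_ids):
        j = target_pos.get(p)
        if j is not None:
            common.append(p)
            ref_idx.append(i)
            tgt_idx.append(j)
    coverage = len(common) / len(reference_probe_ids)
    if len(common) < floor:
        raise ReconstructionError(
            f"only {len(common)} probes match (floor {floor}); "
            f"reference {len(reference_probe_ids)}, target {len(target_probe_ids)}"
        )
    return common, np.array(ref_idx), np.array(tgt_idx), coverage


def match_and_build(reference_probe_ids, projections: np.ndarray,
                    target: MethylationMatrix, floor: int = 100) -> ReconstructionInput:
    common, ref_idx, tgt_idx, coverage = match_probes(
        reference_probe_ids, target.probe_ids, floor
    )
    return ReconstructionInput(
        projections=np.asarray(projections)[ref_idx, :],
        target=target.values[tgt_idx, :],
        probe_ids=common,
        sample_ids=list(target.sample_ids),
        coverage=coverage,
    )


def reconstruct_pcs(rec_input: ReconstructionInput) -> pd.DataFrame:
    """Reconstructed components V~ = norm(Yc^T P), one unit-norm column
    per selected reference PC, indexed by target sample ID."""
    Y = np.asarray(rec_input.target, dtype=float)
    P = np.asarray(rec_input.projections, dtype=float)
    if Y.shape[0] != P.shape[0]:
        raise ReconstructionError(
            f"target has {Y.shape[0]} probes, projections have {P.shape[0]}"
        )
    if rec_input.center_target:
        Y = Y - Y.mean(axis=0, keepdims=True)   # per-sample mean
        Y = Y - Y.mean(axis=1, keepdims=True)   # per-probe offset
    V = Y.T @ P
    norms = np.linalg.norm(V, axis=0)
    for j, nv in enumerate(norms):
        if nv == 0:
            raise ReconstructionError(f"reconstructed column {j} is zero before normalization")
    V = V / norms
    return pd.DataFrame(V, index=rec_input.sample_ids,
                        columns=[f"rpc{j + 1}" for j in range(V.shape[1])])


def validate_reconstruction(reconstructed: pd.DataFrame, traits: dict) -> pd.DataFrame:
    """Pearson r and p of each reconstructed PC against each trait.

    ``traits`` maps trait name -> per-new-sample values in the row order
    of ``reconstructed``.
    """
    if len(reconstructed) < 3:
        raise ReconstructionError("need >= 3 target samples")
    rows = []
    for name, values in traits.items():
        values = np.asarray(values, dtype=float)
        if np.std(values) == 0:
            raise ReconstructionError(f"trait {name!r} is constant")
        for col in reconstructed.columns:
            r, p = _pearson(reconstructed[col].to_numpy(), values)
            rows.append((col, name, r, p, len(values)))
    return pd.DataFrame(rows, columns=["reconstructed_pc", "trait", "r", "p_value", "n"])
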