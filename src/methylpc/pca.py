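"""Sample-space principal component analysis of methylation M-values.

The model operates on an N-probe x M-sample matrix X.  Each sample's mean
M-value is subtracted, the M x M covariance over probes is
eigendecomposed, and the eigenvectors V (one pattern value per sample) are
the principal components with eigenvalues sigma_i^2.  Probe projections
P = XV quantify how much each PC contributes to each probe's pattern; the
projection distribution on PC k has variance equal to the eigenvalue, so
probes driving a pattern are selected as |P_ik| > n*sigma_k.

Because M-values are bimodal over probes (low- vs high-methylated), the
dominant variance component when probe means are left in is a near-uniform
"zeroth PC": a constant per-probe offset carrying no between-sample
pattern.  With ``remove_offset=True`` (the default) this offset direction
is projected out before the eigendecomposition and its explained fraction
reported; the operation is algebraically identical to centering each
probe's row, which keeps it exactly equivalent to the row-centered
pipeline while still reporting the offset's share of variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import MethylationMatrix


class PCAError(ValueError):
    pass


@dataclass
class MethylationPCAResults:
    """Fitted sample-space PCA.

    Attributes
    ----------
    components : ndarray, shape (M, K)
        Orthonormal PC matrix V; column k is PC k's per-sample pattern.
    eigenvalues : ndarray, shape (K,)
        Variances sigma_k^2, sorted descending, 1/(N-1) convention.
    projections : ndarray, shape (N, K)
        P = XV on the centered (and offset-deflated) data; column k has
        variance (N-1)/N-corrected equal to the eigenvalue:
        sum_i P_ik^2 = (N-1) sigma_k^2.
    offset_removed : bool
        Whether the uniform offset direction was deflated.
    offset_fraction : float
        Fraction of total (column-centered) variance carried by the offset
        direction; 0.0 when not removed.
    offset_detected : bool
        Whether the top raw eigenvector actually resembled the uniform
        vector (cosine > 0.99) — i.e. the data had a bimodal probe
        baseline worth deflating.
    """

    model: "MethylationPCA"
    components: np.ndarray
    eigenvalues: np.ndarray
    projections: np.ndarray
    sample_ids: list
    probe_ids: list
    offset_removed: bool = False
    offset_fraction: float = 0.0
    offset_detected: bool = False

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def explained_fraction(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    def scores(self, pc_index: int) -> np.ndarray:
        """Per-sample pattern values of PC ``pc_index`` (1-based)."""
        return self.components[:, _check_pc(pc_index, self.n_components) - 1]

    def projection(self, pc_index: int) -> np.ndarray:
        return self.projections[:, _check_pc(pc_index, self.n_components) - 1]

    def sigma(self, pc_index: int) -> float:
        """Projection-scale standard deviation: sqrt of the eigenvalue."""
        return float(np.sqrt(self.eigenvalues[_check_pc(pc_index, self.n_components) - 1]))

    # ------------------------------------------------------------------
    def select_probes(self, pc_index: int, n_sigma: float, sign: str = "both"):
        """Probes whose projection on a PC exceeds ``n_sigma`` projection SDs.

        The projection SD is the square root of the PC's eigenvalue.
        ``sign`` is 'positive', 'negative' or 'both'; 'both' returns a dict
        with both tails.
        """
        if n_sigma <= 0:
            raise PCAError("n_sigma must be > 0")
        k = _check_pc(pc_index, self.n_components)
        sd = self.sigma(k)
        proj = self.projections[:, k - 1]
        if sd == 0:
            warnings.warn(f"PC{k} has zero eigenvalue; selection is empty")
            pos, neg = set(), set()
        else:
            ids = np.asarray(self.probe_ids, dtype=object)
            pos = set(ids[proj > n_sigma * sd])
            neg = set(ids[proj < -n_sigma * sd])
        if sign == "positive":
            return pos
        if sign == "negative":
            return neg
        if sign == "both":
            return {"positive": pos, "negative": neg}
        raise PCAError(f"sign must be positive/negative/both, got {sign!r}")

    def deflate(self, pc_indices) -> MethylationMatrix:
        """Subtract the rank-1 contribution of the chosen PCs from the data.

        X' = X - sum_k P_k v_k^T over the requested components; X' then has
        zero projection on the removed PCs and unchanged projections on the
        retained ones.
        """
        X = self.model.centered_values.copy()
        for k in pc_indices:
            k = _check_pc(k, self.n_components)
            v = self.components[:, k - 1]
            p = self.projections[:, k - 1]
            X -= np.outer(p, v)
        return MethylationMatrix(
            self.probe_ids, self.sample_ids, X, centered=True,
            column_means=self.model.matrix.column_means,
        )

    # convenience handles into the sibling analysis modules -------------
    def associate(self, meta, traits, subsets=None):
        from . import association

        return association.associate_all_pcs(self, meta, traits, subsets)

    def concordance(self, meta, start_after_pc: int = 3, alpha: float = 0.01, **kw):
        from . import concordance

        return concordance.select_concordant_pcs(self, meta, start_after_pc, alpha, **kw)

    def reconstruct_in(self, target: MethylationMatrix, pc_indices, floor: int = 100):
        from . import reconstruction

        idx = [_check_pc(k, self.n_components) - 1 for k in pc_indices]
        P = self.projections[:, idx]
        rec_input = reconstruction.match_and_build(self.probe_ids, P, target, floor)
        return reconstruction.reconstruct_pcs(rec_input)

    # ------------------------------------------------------------------
    def summary(self, top_k: int = 10) -> pd.DataFrame:
        k = min(top_k, self.n_components)
        return pd.DataFrame(
            {
                "pc": np.arange(1, k + 1),
                "eigenvalue": self.eigenvalues[:k],
                "explained_fraction": self.explained_fraction[:k],
                "cumulative_fraction": np.cumsum(self.explained_fraction[:k]),
            }
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            "Sample-space methylation PCA",
            f"  probes: {len(self.probe_ids)}  samples: {len(self.sample_ids)}",
            f"  offset removed: {self.offset_removed}"
            + (f" (detected, {self.offset_fraction:.1%} of variance)"
               if self.offset_detected else ""),
            self.summary().to_string(index=False),
        ]
        return "\n".join(lines)


class MethylationPCA:
    """Sample-space PCA model over a :class:`MethylationMatrix`.

    ``fit()`` returns a :class:`MethylationPCAResults`.  Requires at least
    as many probes as samples (N >= M >= 2): with fewer probes than
    samples the M x M covariance over probes is rank-deficient by
    construction and sample-space PCA is not meaningful.
    """

    def __init__(self, matrix: MethylationMatrix, remove_offset: bool = True):
        if matrix.n_samples > matrix.n_probes:
            raise PCAError(
                f"sample-space PCA needs N >= M; got N={matrix.n_probes} probes, "
                f"M={matrix.n_samples} samples"
            )
        self.matrix = matrix.center_columns()
        self.remove_offset = bool(remove_offset)
        self.centered_values: np.ndarray | None = None

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kw) -> "MethylationPCA":
        m = MethylationMatrix(list(frame.index), list(frame.columns), frame.to_numpy(float))
        return cls(m, **kw)

    def fit(self) -> MethylationPCAResults:
        X = self.matrix.values
        n, m = X.shape
        offset_fraction = 0.0
        offset_detected = False

        if self.remove_offset:
            total_var = float((X * X).sum())
            u = np.full(m, 1.0 / np.sqrt(m))
            # detect whether the dominant raw component is offset-like
            cov_raw = (X.T @ X) / (n - 1)
            w_raw, v_raw = np.linalg.eigh(cov_raw)
            top = v_raw[:, -1]
            offset_detected = abs(float(top @ u)) > 0.99
            coef = X @ u
            X = X - np.outer(coef, u)  # exact uniform-direction deflation
            if total_var > 0:
                offset_fraction = float((coef * coef).sum()) / total_var
        self.centered_values = X

        cov = (X.T @ X) / (n - 1)
        if self.remove_offset:
            # eigendecompose within the orthogonal complement of the uniform
            # direction, so every component is exactly offset-free
            u = np.full(m, 1.0 / np.sqrt(m))
            q, _ = np.linalg.qr(np.column_stack([u, np.eye(m)[:, : m - 1]]))
            B = q[:, 1:]
            wr, vr = np.linalg.eigh(B.T @ cov @ B)
            w, v = wr, B @ vr
        else:
            w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w = np.clip(w[order], 0.0, None)
        v = v[:, order]

        v = _fix_signs(v)
        P = X @ v
        return MethylationPCAResults(
            model=self,
            components=v,
            eigenvalues=w,
            projections=P,
            sample_ids=list(self.matrix.sample_ids),
            probe_ids=list(self.matrix.probe_ids),
            offset_removed=self.remove_offset,
            offset_fraction=offset_fraction,
            offset_detected=offset_detected,
        )


def _fix_signs(v: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|entry| component is positive.

    PC signs are arbitrary; this convention makes output reproducible.
    Ties on |entry| go to the earliest sample.
    """
    v = v.copy()
    for k in range(v.shape[1]):
        col = v[:, k]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            v[:, k] = -col
    return v


def _check_pc(pc_index: int, n: int) -> int:
    if not 1 <= pc_index <= n:
        raise PCAError(f"PC index {pc_index} out of range 1..{n}")
    return int(pc_index)


# ---------------------------------------------------------------------------
# functional interface


def fit_pca(matrix: MethylationMatrix, remove_offset: bool = True) -> MethylationPCAResults:
    """Fit sample-space PCA; see :class:`MethylationPCA`."""
    return MethylationPCA(matrix, remove_offset=remove_offset).fit()


def project_probes(matrix: MethylationMatrix, result: MethylationPCAResults) -> np.ndarray:
    """Project a probe x sample matrix onto fitted components: P = XV.

    The matrix must be in the same centering state as the fit used
    (column-centered, offset deflated when the fit removed it).
    """
    if matrix.n_samples != result.components.shape[0]:
        raise PCAError(
            f"matrix has {matrix.n_samples} samples, components expect "
            f"{result.components.shape[0]}"
        )
    return matrix.values @ result.components


def select_probes_by_projection(result, pc_index, n_sigma, sign="both"):
    return result.select_probes(pc_index, n_sigma, sign)


def deflate_components(matrix, result: MethylationPCAResults, pc_indices) -> MethylationMatrix:
    """Rank-1 deflation of selected PCs; see ``MethylationPCAResults.deflate``."""
    del matrix  # the fit's centered data is authoritative
    return result.deflate(pc_indices)


def select_high_variance_probes(matrix: MethylationMatrix, k_sigma: float) -> set:
    """Probes with outlying variance across all samples.

    Per-probe variance is computed across samples (ddof=1); probes whose
    variance exceeds mean + ``k_sigma`` * SD of the probe-variance
    distribution are returned.  The reference distribution for the cutoff
    is the empirical distribution of per-probe variances.
    """
    if k_sigma <= 0:
        raise PCAError("k_sigma must be > 0")
    var = matrix.values.var(axis=1, ddof=1)
    mu, sd = var.mean(), var.std(ddof=1)
    if sd == 0:
        return set()
    ids = np.asarray(matrix.probe_ids, dtype=object)
    return set(ids[var > mu + k_sigma * sd])
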