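"""Genomic-context enrichment of projection-selected probe subsets.

Enrichment of a probe subset against a background universe is scored with
a binomial null: with background proportion p = n_bg / N_bg, the subset
count n_exp is compared with mu = p * N_exp under

    mu     = (n_bg / N_bg) * N_exp
    sigma2 = (1 - mu / N_exp) * mu
    Z      = (n_exp - mu) / sigma

Category enrichments (CpG-density class HC/IC/ICshore/LC, intron/exon,
CH probes) use one such test per category level; spatial enrichment around
transcription start sites bins signed TSS distances (default 167 bp bins
within +/-2.5 kbp) and scores each bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ProbeAnnotation
from .pca import MethylationPCAResults


class EnrichmentError(ValueError):
    pass


@dataclass
class SpatialEnrichment:
    bin_edges: np.ndarray      # len B+1, signed bp relative to TSS
    n_exp: np.ndarray
    n_bg: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    z: np.ndarray
    N_exp: int
    N_bg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "n_exp": self.n_exp,
            "n_bg": self.n_bg,
            "mu": self.mu,
            "sigma2": self.sigma2,
            "z": self.z,
        })


def binomial_z(n_exp: int, N_exp: int, n_bg: int, N_bg: int):
    """(mu, sigma2, Z) of the binomial enrichment null; see module docs."""
    if N_bg <= 0 or N_exp <= 0:
        raise EnrichmentError("N_bg and N_exp must be positive")
    if n_bg > N_bg or n_exp > N_exp:
        raise EnrichmentError("count exceeds its set size")
    p = n_bg / N_bg
    mu = p * N_exp
    sigma2 = (1.0 - mu / N_exp) * mu
    if sigma2 == 0:
        raise EnrichmentError(f"degenerate null (p={p}); Z undefined")
    z = (n_exp - mu) / math.sqrt(sigma2)
    return mu, sigma2, z


def category_enrichment(subset: set, background: set, annotation: ProbeAnnotation,
                        category_field: str) -> pd.DataFrame:
    """Per-category enrichment of ``subset`` against ``background``.

    ``category_field`` is one of the annotation columns (density_class,
    region_class, is_CH).  Categories with a degenerate null (present in
    all or none of the background) get Z = NaN with a warning.
    """
    if not subset:
        raise EnrichmentError("empty subset")
    if not subset <= background:
        raise EnrichmentError("subset must be contained in background")
    ann = annotation.indexed()
    cats = ann.loc[sorted(background), category_field]
    sub_cats = ann.loc[sorted(subset), category_field]
    N_bg, N_exp = len(background), len(subset)
    rows = []
    for level in sorted(cats.unique(), key=str):
        n_bg = int((cats == level).sum())
        n_exp = int((sub_cats == level).sum())
        fold = (n_exp / N_exp) / (n_bg / N_bg) if n_bg else np.inf
        try:
            mu, sigma2, z = binomial_z(n_exp, N_exp, n_bg, N_bg)
        except EnrichmentError:
            warnings.warn(f"category {level!r}: degenerate null, Z undefined")
            mu, sigma2, z = float(n_bg / N_bg * N_exp), 0.0, np.nan
        rows.append((level, n_exp, N_exp, n_bg, N_bg, fold, z))
    return pd.DataFrame(rows, columns=["category", "n_exp", "N_exp", "n_bg",
                                       "N_bg", "fold", "z"])


def tss_spatial_enrichment(subset: set, background: set, probe_gene_map: dict,
                           bin_bp: int = 167, window_bp: int = 2500) -> SpatialEnrichment:
    """Binned TSS-distance enrichment of ``subset`` vs ``background``.

    Both sets are restricted to probes present in ``probe_gene_map``
    (probe -> (gene, signed distance)).  Bins of width ``bin_bp`` are
    anchored at -window_bp; the last bin is truncated at +window_bp, and a
    distance falling exactly on an interior edge belongs to the bin on its
    right.
    """
    def distances(probes):
        return np.array([probe_gene_map[p][1] for p in sorted(probes)
                         if p in probe_gene_map], dtype=float)

    d_exp = distances(subset)
    d_bg = distances(background)
    if d_exp.size == 0:
        raise EnrichmentError("subset has no probes in the probe-gene map")
    if d_bg.size == 0:
        raise EnrichmentError("background has no probes in the probe-gene map")
    n_bins = math.ceil(2 * window_bp / bin_bp)
    edges = -window_bp + bin_bp * np.arange(n_bins + 1, dtype=float)
    edges[-1] = window_bp  # truncate the last bin

    def bin_counts(d):
        idx = np.floor((d + window_bp) / bin_bp).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        return np.bincount(idx, minlength=n_bins)

    n_exp = bin_counts(d_exp)
    n_bg = bin_counts(d_bg)
    N_exp, N_bg = int(d_exp.size), int(d_bg.size)
    mu = np.empty(n_bins)
    sigma2 = np.empty(n_bins)
    z = np.full(n_bins, np.nan)
    for b in range(n_bins):
        try:
            mu[b], sigma2[b], z[b] = binomial_z(int(n_exp[b]), N_exp,
                                                int(n_bg[b]), N_bg)
        except EnrichmentError:
            mu[b] = n_bg[b] / N_bg * N_exp
            sigma2[b] = 0.0
    return SpatialEnrichment(edges, n_exp, n_bg, mu, sigma2, z, N_exp, N_bg)


def gene_sets_from_projections(result: MethylationPCAResults, pc_index: int,
                               probe_gene_map: dict, n_sigma: float = 2.0):
    """Genes hit by the positive / negative projection tails of a PC.

    A gene enters a set when at least one of its mapped probes passes the
    corresponding +/- ``n_sigma`` projection threshold.
    """
    if not probe_gene_map:
        raise EnrichmentError("empty probe-gene map")
    tails = result.select_probes(pc_index, n_sigma, "both")
    out = {}
    for side in ("positive", "negative"):
        out[side] = {probe_gene_map[p][0] for p in tails[side] if p in probe_gene_map}
    return out


def overlap_vs_expected(set_a: set, set_b: set, universe_size: int):
    """Observed vs chance overlap of two gene sets from one universe.

    Expected overlap under independent uniform draws is |a|*|b|/G; the
    ratio is observed/expected (0 when expected is 0 and observed is 0,
    inf when expected is 0 but observed is not).
    """
    if universe_size <= 0:
        raise EnrichmentError("universe_size must be positive")
    if len(set_a) > universe_size or len(set_b) > universe_size:
        raise EnrichmentError("set larger than universe")
    observed = len(set_a & set_b)
    expected = len(set_a) * len(set_b) / universe_size
    if expected == 0:
        ratio = 0.0 if observed == 0 else np.inf
    else:
        ratio = observed / expected
    return observed, expected, ratio
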