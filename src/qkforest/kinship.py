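"""Marker-based kinship for dominant haploid-scored data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import MarkerMatrix
from .popstruct import jaccard_distance

__all__ = [
    "KinshipMatrix",
    "kinship_jaccard",
    "kinship_freq_corrected",
    "kinship_histogram",
]


@dataclass
class KinshipMatrix:
    """Symmetric accession similarity matrix; diagonal fixed at 1.

    The unit-diagonal similarity convention makes the polygenic variance in
    V_G = sigma^2 * K interpretable as the genotypic variance of a single
    non-inbred accession.
    """

    values: np.ndarray
    accession_ids: list[str]
    estimator: str = "freqcorr"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("kinship diagonal must be 1")
        off = self.values[~np.eye(len(self.accession_ids), dtype=bool)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal kinship values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.accession_ids, name="accession"),
                            columns=self.accession_ids)


def kinship_jaccard(markers: MarkerMatrix) -> KinshipMatrix:
    """Jaccard band-sharing similarity, K = 1 - D elementwise."""
    D = jaccard_distance(markers)
    K = 1.0 - D.values
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(values=K, accession_ids=list(markers.accession_ids),
                         estimator="jaccard")


def kinship_freq_corrected(markers: MarkerMatrix) -> KinshipMatrix:
    """Allele-sharing kinship corrected for marker frequency.

    K_ij = mean_j [(x_ij - p_j)(x_kj - p_j) / (p_j (1 - p_j))], with negative
    values truncated to 0 and the diagonal set to 1.  Requires polymorphic
    markers (run the frequency filter first).
    """
    p = markers.allele_freq
    if (p <= 0).any() or (p >= 1).any():
        raise ValueError(
            "monomorphic marker present; apply filter_markers before kinship")
    X = markers.scores.astype(float)
    Z = (X - p) / np.sqrt(p * (1.0 - p))
    S = (Z @ Z.T) / markers.n_markers
    d = np.sqrt(np.diag(S))
    K = S / np.outer(d, d)  # similarity scale: duplicates score exactly 1
    K = np.clip(K, 0.0, 1.0)
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(values=K, accession_ids=list(markers.accession_ids),
                         estimator="freqcorr")


def kinship_histogram(K: KinshipMatrix, bin_width: float = 0.05) -> pd.DataFrame:
    """Class frequencies (%) of off-diagonal kinship values.

    Bins are [0, w), [w, 2w), ... with the final bin closed at 1; percentages
    sum to 100.
    """
    n = K.values.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = K.values[iu]
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    counts, _ = np.histogram(vals, bins=edges)
    pct = 100.0 * counts / vals.size if vals.size else np.zeros_like(counts, dtype=float)
    return pd.DataFrame({
        "bin_low": edges[:-1],
        "bin_high": edges[1:],
        "count": counts,
        "percent": pct,
    })
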