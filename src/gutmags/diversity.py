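"""Hill-number diversity and principal coordinates analysis.

Hill numbers express diversity as effective numbers of MAGs: order
q = 0 is richness, q = 1 the exponential of Shannon entropy, q = 2 the
inverse Simpson concentration.  Ordination uses classical metric
scaling (PCoA) of a binary (Jaccard) distance between the
presence/absence profiles of samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import CoverageMatrix, CoverageState, Dataset


def hill_number(p: np.ndarray, q: float) -> float:
    """Effective number of order ``q`` for relative abundances ``p``.

    ``p`` must be nonnegative and sum to 1 (within 1e-9) over its
    nonzero support.  q = 0 counts nonzero entries; q = 1 uses the
    Shannon limit exp(-sum p ln p); otherwise (sum p^q)^(1/(1-q)).
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("relative abundances must be nonnegative")
    nz = p[p > 0]
    if nz.size == 0:
        raise ValueError("empty community")
    if abs(nz.sum() - 1.0) > 1e-9:
        raise ValueError(f"abundances sum to {nz.sum()!r}, expected 1")
    if q < 0:
        raise ValueError("order q must be >= 0")
    if q == 0:
        return float(nz.size)
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(nz * np.log(nz))))
    return float(np.sum(nz ** q) ** (1.0 / (1.0 - q)))


@dataclass
class DiversityProfile:
    """Per-sample effective numbers D0, D1, D2 with design annotations."""

    table: pd.DataFrame  # index sample_id; D0, D1, D2, sample_type, substrate


def diversity_profile(coverage: CoverageMatrix,
                      dataset: Dataset | None = None) -> DiversityProfile:
    """D0, D1, D2 for every sample of a relative-abundance matrix."""
    if coverage.state is not CoverageState.RELATIVE:
        raise ValueError("diversity_profile expects a relative-abundance matrix")
    rows = {}
    for sample in coverage.sample_ids:
        p = coverage.values[sample].to_numpy()
        rows[sample] = {f"D{q}": hill_number(p, q) for q in (0, 1, 2)}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    if dataset is not None:
        meta = dataset.sample_frame().set_index("sample_id")
        table = table.join(meta[["sample_type", "substrate"]])
    return DiversityProfile(table=table)


def binary_distance(presence: pd.DataFrame) -> pd.DataFrame:
    """Jaccard distance between sample presence/absence profiles.

    ``presence`` is boolean MAG x sample.  d(A, B) = (b + c) /
    (a + b + c) with a = shared presences and b, c the exclusive ones;
    joint absences are ignored; two empty samples are at distance 0.
    """
    if presence.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = presence.T.to_numpy(dtype=bool)
    d = squareform(pdist(X, metric="jaccard"))
    return pd.DataFrame(d, index=presence.columns, columns=presence.columns)


@dataclass
class PcoaResult:
    """Sample coordinates, eigenvalues and percent variance per axis."""

    coordinates: pd.DataFrame  # sample x axis ("PC1", ...)
    eigenvalues: np.ndarray    # retained positive eigenvalues, descending
    percent_variance: np.ndarray


def pcoa(dist: pd.DataFrame, negative_eigenvalue_policy: str = "drop") -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    Double-centers -1/2 D^2, eigendecomposes, and retains axes with
    positive eigenvalues (coordinates are eigenvectors scaled by the
    square root of their eigenvalue).  Percent variance is computed
    over the positive eigenvalues.  ``negative_eigenvalue_policy``:
    'drop' (default) discards negative axes; 'lingoes' adds the Lingoes
    constant (-smallest negative eigenvalue) to squared off-diagonal
    distances first, making the configuration Euclidean.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be nonnegative")
    n = D.shape[0]
    if negative_eigenvalue_policy not in ("drop", "lingoes"):
        raise ValueError(f"unknown policy {negative_eigenvalue_policy!r}")

    def _eigen(D2: np.ndarray):
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D2 @ J
        vals, vecs = np.linalg.eigh((B + B.T) / 2)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = _eigen(D ** 2)
    if negative_eigenvalue_policy == "lingoes" and vals[-1] < -1e-12:
        c = -vals[-1]
        D2 = D ** 2 + 2.0 * c * (1 - np.eye(n))
        vals, vecs = _eigen(D2)

    tol = max(np.abs(vals).max(), 1.0) * 1e-12
    keep = vals > tol
    vals_pos = vals[keep]
    coords = vecs[:, keep] * np.sqrt(vals_pos)
    pct = 100.0 * vals_pos / vals_pos.sum() if vals_pos.size else np.array([])
    labels = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coordinates = pd.DataFrame(coords, index=dist.index, columns=labels)
    return PcoaResult(coordinates=coordinates, eigenvalues=vals_pos,
                      percent_variance=pct)
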