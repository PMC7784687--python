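"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np


def nearest_pd(matrix: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Symmetrize and clip eigenvalues at `floor`.

    Used when a covariance assembled from a printed correlation table is not
    positive definite; the projection changes the implied correlations
    slightly, so callers should report the realized matrix, not the target.
    """
    sym = 0.5 * (matrix + matrix.T)
    w, v = np.linalg.eigh(sym)
    return (v * np.clip(w, floor, None)) @ v.T


def safe_cholesky(matrix: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Lower Cholesky factor, with one jitter retry for PSD-but-singular input."""
    try:
        return np.linalg.cholesky(matrix)
    except np.linalg.LinAlgError:
        bump = jitter * max(1.0, float(np.trace(matrix)) / len(matrix))
        return np.linalg.cholesky(matrix + bump * np.eye(len(matrix)))
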