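"""Mass-corrected cluster permutation utilities shared across analyses."""

from __future__ import annotations

import numpy as np


def find_clusters(above: np.ndarray) -> list[slice]:
    """Contiguous runs of True in a boolean 1-D mask."""
    above = np.asarray(above, dtype=bool)
    if above.ndim != 1:
        raise ValueError("expected a 1-D mask")
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    return [slice(a, b) for a, b in zip(edges[::2], edges[1::2])]


def max_cluster_mass(deviation: np.ndarray) -> float:
    """Largest summed positive-cluster mass of a deviation curve."""
    masses = [deviation[c].sum() for c in find_clusters(deviation > 0)]
    return float(max(masses)) if masses else 0.0


def cluster_mass_mask(
    observed: np.ndarray,
    null_curves: np.ndarray,
    percentile: float = 97.5,
) -> np.ndarray:
    """Boolean mask of observed clusters exceeding the max-mass null.

    ``observed`` is a deviation curve (already baseline-subtracted);
    ``null_curves`` is (n_shuffles, n_times) of deviation curves under the
    null.  The threshold is the requested percentile of the distribution of
    each shuffle's maximum positive cluster mass.
    """
    null_curves = np.atleast_2d(null_curves)
    null_max = np.array([max_cluster_mass(c) for c in null_curves])
    threshold = float(np.percentile(null_max, percentile))
    mask = np.zeros(observed.shape, dtype=bool)
    for c in find_clusters(observed > 0):
        if observed[c].sum() > threshold:
            mask[c] = True
    return mask
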