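"""Independent brute-force oracles used by the test suite.

These deliberately avoid scipy.ndimage / skimage so they can serve as
independent checks of the pipeline's distance-transform and labeling
paths on small inputs.
"""

from __future__ import annotations

import numpy as np


def brute_force_distance(mask: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distance of each foreground pixel to the
    nearest background pixel (in pixels)."""
    mask = np.asarray(mask, bool)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, float)
    for r, c in np.argwhere(mask):
        d2 = (bg[:, 0] - r) ** 2 + (bg[:, 1] - c) ** 2
        out[r, c] = np.sqrt(d2.min())
    return out


def flood_fill_labels(mask: np.ndarray) -> np.ndarray:
    """8-connected component labeling by explicit stack-based flood fill."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, int)
    next_label = 0
    for seed in map(tuple, np.argwhere(mask)):
        if labels[seed]:
            continue
        next_label += 1
        stack = [seed]
        labels[seed] = next_label
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < mask.shape[0]
                        and 0 <= cc < mask.shape[1]
                        and mask[rr, cc]
                        and not labels[rr, cc]
                    ):
                        labels[rr, cc] = next_label
                        stack.append((rr, cc))
    return labels


def moment_ellipse_axes(mask: np.ndarray) -> tuple[float, float]:
    """(major, minor) full axis lengths of the moment-matched ellipse,
    from the eigenvalues of the pixel-coordinate covariance matrix."""
    pts = np.argwhere(np.asarray(mask, bool)).astype(float)
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    return 4.0 * np.sqrt(eig[0]), 4.0 * np.sqrt(eig[1])
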