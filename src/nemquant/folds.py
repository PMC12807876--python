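"""Nuclear-envelope fold counting by skeleton branch-point morphometrics.

Shrivelling/invagination of the NE creates junctions in a skeletonized
outline of the mid-slice envelope.  The fold metric is the number of
branch points after condensing nearby junctions (noise on the skeleton
tends to split one true junction into a small cluster of raw ones):

1. single-scale ridge enhancement of the NE marker at the filament
   thickness scale (default 1.6, ~3-4 px structures), triangle threshold;
2. morphological thinning to a 1-px outline (topology preserved);
3. branch points = skeleton pixels with >= 3 skeleton neighbours in the
   8-neighbourhood, condensed by single-linkage clustering at a 4-px radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage import filters, morphology

from ._util import remove_small

__all__ = ["FoldMetric", "lamina_outline_mask", "outline_skeleton", "fold_count"]


@dataclass
class FoldMetric:
    raw_branch_points: int
    condensed_branch_points: int
    skeleton: np.ndarray
    normalized_folds: Optional[float] = None

    def __post_init__(self) -> None:
        assert self.condensed_branch_points <= self.raw_branch_points


def lamina_outline_mask(mid_slice: np.ndarray, thickness: float = 1.6) -> np.ndarray:
    """Ridge-enhance the NE on a mid-slice and threshold to a binary mask.

    Only a light Gaussian blur precedes the single-scale Sato (Hessian
    tubeness) filter -- no rolling ball or normalization, which would erase
    membrane detail.  The response is thresholded with the triangle method,
    which tolerates the heavy background-peak histogram of ridge responses.
    """
    img = np.asarray(mid_slice, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D mid-slice, got {img.ndim}-D")
    if img.max() <= img.min():
        return np.zeros(img.shape, bool)
    img = ndi.gaussian_filter(img, sigma=0.5)
    response = filters.sato(img, sigmas=[thickness], black_ridges=False)
    if response.max() <= 0:
        return np.zeros(img.shape, bool)
    # Otsu keeps the ridge core; lower thresholds (e.g. triangle) admit the
    # wavy response halo, whose skeleton grows hairs and phantom junctions
    thr = filters.threshold_otsu(response[response > 0])
    mask = response > thr
    return remove_small(mask, 8)


def outline_skeleton(mask: np.ndarray, prune_px: int = 5) -> np.ndarray:
    """Thin a binary mask to a 1-px skeleton (loops preserved).

    A filled disk thins to a point (or tiny cluster) by the thinning
    convention; a ring thins to a 1-px closed loop.  Open side branches
    shorter than ``prune_px`` -- hairs that thinning grows out of boundary
    bumps -- are removed by iterative endpoint deletion; closed loops have
    no endpoints and are untouched, and genuine fold spurs (~10 px and
    longer) only lose their tips.
    """
    sk = morphology.skeletonize(np.asarray(mask, bool))
    for _ in range(prune_px):
        nb = ndi.convolve(sk.astype(np.uint8), _NEIGHBOUR_KERNEL, mode="constant")
        endpoints = sk & (nb <= 1)
        if not endpoints.any():
            break
        sk = sk & ~endpoints
    return _declump(sk)


def _declump(sk: np.ndarray) -> np.ndarray:
    """Remove one redundant pixel from every 2x2 skeleton block.

    Thinning can leave 2x2 clumps at junctions; a clump smears the
    crossing number over four pixels and hides the junction.  Deleting
    the clump pixel with the most neighbours restores a sharp Y/X node
    without disconnecting the skeleton.
    """
    sk = sk.copy()
    while True:
        block = sk[:-1, :-1] & sk[:-1, 1:] & sk[1:, :-1] & sk[1:, 1:]
        ys, xs = np.nonzero(block)
        if not len(ys):
            return sk
        y, x = int(ys[0]), int(xs[0])
        nb = ndi.convolve(sk.astype(int), _NEIGHBOUR_KERNEL, mode="constant")
        cand = sorted([(y, x), (y, x + 1), (y + 1, x), (y + 1, x + 1)],
                      key=lambda p: -int(nb[p]))
        sk[cand[0]] = False


_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
# cyclic order of the 8-neighbourhood for arm counting
_CYCLE = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def _arm_count(sk: np.ndarray) -> np.ndarray:
    """Number of distinct skeleton arms at each pixel (crossing number).

    Counts 0->1 transitions around the cyclic 8-neighbourhood.  A raw
    neighbour count misfires on the staircase corners of any rasterized
    curve (3 neighbours, still just a line); the transition count is what
    distinguishes a through-pixel (2 arms) from a junction (>= 3 arms).
    """
    padded = np.pad(sk, 1).astype(np.uint8)
    rings = np.stack([padded[1 + dy: padded.shape[0] - 1 + dy,
                             1 + dx: padded.shape[1] - 1 + dx]
                      for dy, dx in _CYCLE])
    nxt = np.roll(rings, -1, axis=0)
    return ((rings == 0) & (nxt == 1)).sum(axis=0)


def fold_count(
    skeleton: np.ndarray,
    neighbour_threshold: int = 3,
    condense_radius_px: float = 4.0,
    reference_count: Optional[int] = None,
) -> FoldMetric:
    """Count condensed skeleton branch points.

    Raw branch points are skeleton pixels where at least
    ``neighbour_threshold`` distinct skeleton arms meet (>= 3 catches Y
    junctions; set 4 for the stricter crossing definition); a plain loop
    or line has no junctions under this rule.  Condensation merges raw
    points by single-linkage at ``condense_radius_px`` -- connected
    components of the radius graph -- and counts clusters.
    ``reference_count`` (e.g. the frame-0 count) yields
    ``normalized_folds``; the count is invariant to translation and to
    rotations by multiples of 90 degrees.
    """
    sk = np.asarray(skeleton, bool)
    branch = sk & (_arm_count(sk) >= neighbour_threshold)
    pts = np.argwhere(branch)
    raw = len(pts)
    if raw == 0:
        condensed = 0
    else:
        tree = cKDTree(pts.astype(float))
        pairs = tree.query_pairs(condense_radius_px, output_type="ndarray")
        if len(pairs):
            data = np.ones(len(pairs))
            adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(raw, raw))
            condensed = int(connected_components(adj, directed=False)[0])
        else:
            condensed = raw
    norm = None
    if reference_count is not None and reference_count > 0:
        norm = condensed / reference_count
    return FoldMetric(raw_branch_points=raw, condensed_branch_points=condensed,
                      skeleton=sk, normalized_folds=norm)
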