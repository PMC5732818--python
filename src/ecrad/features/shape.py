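"""3D shape descriptors of the tumor mask.

Four conventional morphological metrics: physical volume, size (longest 3D
diameter), solidity (fraction of the convex hull occupied) and eccentricity
of the voxel point cloud.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError


def shape_features(mask: np.ndarray,
                   spacing: tuple[float, float, float]) -> dict[str, float]:
    """Compute volume (mm^3), size (mm), solidity and eccentricity.

    * volume — voxel count times voxel volume.
    * size — maximum pairwise Euclidean distance between in-mask voxel
      centers (the longest lesion diameter).
    * solidity — voxel count divided by the number of voxel centers inside
      the convex hull of the mask.
    * eccentricity — ``sqrt(1 - λ_min/λ_max)`` from the principal-component
      eigenvalues of the voxel coordinates; 0 for a sphere, → 1 for a rod.

    Degenerate masks (single voxel, collinear/coplanar voxels) fall back to
    size from direct pairwise distances, solidity 1 and eccentricity from
    whatever axes are defined.
    """
    mask = np.asarray(mask).astype(bool)
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("shape features require a nonempty mask")
    spacing = np.asarray(spacing, dtype=float)
    pts = idx * spacing
    n_vox = len(pts)
    voxel_volume = float(np.prod(spacing))
    volume = n_vox * voxel_volume

    if n_vox == 1:
        return {"volume": volume, "size": 0.0, "solidity": 1.0,
                "eccentricity": 0.0}

    # longest diameter: pairwise distances among hull vertices (or all
    # points when the hull is degenerate, e.g. coplanar voxels)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        hull = None
    cand = pts[hull.vertices] if hull is not None else pts
    diff = cand[:, None, :] - cand[None, :, :]
    size = float(np.sqrt((diff ** 2).sum(-1)).max())

    # solidity via voxel-center membership in the hull (half-space test)
    if hull is not None:
        lo = idx.min(axis=0)
        hi = idx.max(axis=0)
        grid = np.stack(np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)],
                                    indexing="ij"), axis=-1).reshape(-1, 3)
        dist = (grid * spacing) @ hull.equations[:, :3].T + hull.equations[:, 3]
        n_hull = int(np.all(dist <= 1e-9, axis=1).sum())
        solidity = n_vox / n_hull if n_hull > 0 else 1.0
    else:
        solidity = 1.0

    cov = np.cov(pts.T)
    eig = np.sort(np.linalg.eigvalsh(cov))
    if eig[-1] <= 0:
        eccentricity = 0.0
    else:
        eccentricity = float(np.sqrt(max(0.0, 1.0 - eig[0] / eig[-1])))
    return {"volume": volume, "size": size, "solidity": float(min(solidity, 1.0)),
            "eccentricity": eccentricity}
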