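"""Independent geometric oracle for the ternary partition tests."""

import numpy as np

from clonebow import colors


def oracle_region(point: np.ndarray) -> int:
    """Brute-force point-in-triangle location over all 25 region triangles
    (barycentric coordinates, interior test with tolerance)."""
    hits = []
    for idx in range(colors.N_REGIONS):
        verts = colors.region_triangle(idx)  # (3, 3) simplex points
        # solve point = sum_i w_i * vert_i with sum w_i = 1
        a = np.vstack([verts.T[:2], np.ones(3)])
        b = np.array([point[0], point[1], 1.0])
        w = np.linalg.solve(a, b)
        if (w > -1e-12).all():
            hits.append(idx)
    assert hits, f"point {point} in no triangle"
    return hits[0]
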