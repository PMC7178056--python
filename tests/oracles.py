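"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: rotation-space
search instead of the SVD solution, an all-pairs double loop instead of
the vectorized contact map, 3D grid quadrature instead of the analytic
descreening integral.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from mdligand.metrics import _sphere_points


def rmsd_of_rotation(rotvec, mobile_c, reference_c):
    rot = Rotation.from_rotvec(rotvec).as_matrix()
    moved = mobile_c @ rot.T
    return float(np.sqrt(np.mean(np.sum((moved - reference_c) ** 2, axis=1))))


def brute_force_min_rmsd(mobile, reference, n_starts=30):
    """Minimum RMSD over all proper rotations by multi-start local search."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    axes = _sphere_points(max(n_starts, 6))
    starts = [np.zeros(3)]
    for k, axis in enumerate(axes[:n_starts]):
        angle = np.pi * (0.3 + 1.4 * (k % 5) / 5.0)
        starts.append(axis * angle)
    best = np.inf
    for s in starts:
        res = minimize(
            rmsd_of_rotation, s, args=(mc, rc), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
        )
        best = min(best, res.fun)
    return best


def brute_force_contact_map(coords_frames, topology, ids_a, ids_b, cutoff):
    """Fraction of frames with min inter-group atom distance < cutoff,
    per residue pair, via an explicit double loop."""
    res_a = sorted({int(topology.residue_index[i]) for i in ids_a})
    res_b = sorted({int(topology.residue_index[i]) for i in ids_b})
    counts = np.zeros((len(res_a), len(res_b)))
    for frame in coords_frames:
        for i, ra in enumerate(res_a):
            aa = [x for x in ids_a if topology.residue_index[x] == ra]
            for j, rb in enumerate(res_b):
                bb = [x for x in ids_b if topology.residue_index[x] == rb]
                dmin = min(
                    float(np.linalg.norm(frame[p] - frame[q]))
                    for p in aa
                    for q in bb
                )
                if dmin < cutoff:
                    counts[i, j] += 1
    return counts / len(coords_frames)


def numeric_descreening_integral(rho_i, s_j, distance, n=260):
    """(1/4pi) * integral of 1/r^4 over the scaled sphere of atom j,
    excluding the region inside atom i's own radius; grid quadrature."""
    xs = np.linspace(-s_j, s_j, n)
    dv = (2.0 * s_j / n) ** 3
    gx, gy, gz = np.meshgrid(xs, xs, xs, indexing="ij")
    inside_j = gx**2 + gy**2 + gz**2 <= s_j**2
    px = gx[inside_j] + distance
    r2 = px**2 + gy[inside_j] ** 2 + gz[inside_j] ** 2
    outside_i = r2 > rho_i**2
    return float(np.sum(1.0 / r2[outside_i] ** 2) * dv / (4.0 * np.pi))


def plane_fit_rms(points):
    """RMS residual of the least-squares plane through points (SVD-free path:
    direct normal search over the unit sphere refined by optimization)."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)

    def residual(angles):
        t, p = angles
        n = np.array(
            [np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)]
        )
        return float(np.mean((centered @ n) ** 2))

    best = np.inf
    for t0 in np.linspace(0.1, np.pi - 0.1, 8):
        for p0 in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            res = minimize(residual, [t0, p0], method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-18})
            best = min(best, res.fun)
    return float(np.sqrt(best))
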