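"""Independent oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: the triangulation
oracle minimizes reprojection error by coarse depth search plus nonlinear
refinement (never touching the DLT solver), and the noise-propagation
oracle predicts the lip-aperture SD from a numerical delta-method Jacobian.
"""

import numpy as np
import scipy.optimize

from lipstereo.geometry import StereoRig, project, undistort_points
from lipstereo.kinematics import lip_aperture
from lipstereo.geometry import triangulate


def triangulate_nonlinear(rig: StereoRig, left_px, right_px) -> np.ndarray:
    """Reprojection-error-minimizing triangulation of a single point pair.

    Coarse search along the left-camera ray over depth, then unconstrained
    least-squares refinement of the 3D point against both pixel
    observations.
    """
    left_px = np.asarray(left_px, float)
    right_px = np.asarray(right_px, float)
    ray = np.append(undistort_points(rig.left, left_px), 1.0)

    def residual(X):
        return np.concatenate(
            [project(rig.left, X) - left_px, project(rig.right, X) - right_px]
        )

    depths = np.linspace(300.0, 1500.0, 60)
    costs = [np.sum(residual(d * ray) ** 2) for d in depths]
    x0 = depths[int(np.argmin(costs))] * ray
    sol = scipy.optimize.least_squares(residual, x0, xtol=1e-15, ftol=1e-15)
    return sol.x


def predict_la_sd(rig: StereoRig, upper, lower, sigma_px: float, h: float = 1e-3):
    """Delta-method prediction of the lip-aperture SD under iid pixel jitter.

    Numerically differentiates LA with respect to the 8 observed pixel
    coordinates (2 landmarks x 2 cameras x 2 axes) at the true geometry;
    for iid noise of SD sigma on every coordinate, SD(LA) ~= sigma * ||J||.
    """
    upper = np.asarray(upper, float)
    lower = np.asarray(lower, float)
    base = np.concatenate(
        [
            project(rig.left, upper),
            project(rig.right, upper),
            project(rig.left, lower),
            project(rig.right, lower),
        ]
    )

    def la_of(px8):
        u = triangulate(rig, px8[0:2], px8[2:4])
        l = triangulate(rig, px8[4:6], px8[6:8])
        return float(lip_aperture(u[None, :], l[None, :], rate=1.0).values[0])

    J = np.empty(8)
    for k in range(8):
        plus = base.copy()
        minus = base.copy()
        plus[k] += h
        minus[k] -= h
        J[k] = (la_of(plus) - la_of(minus)) / (2 * h)
    return sigma_px * float(np.linalg.norm(J))
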