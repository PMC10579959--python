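"""Rigid point-to-plane ICP registration.

The core operation aligns a *moving* imaging anatomy with a *fixed* EAM
anatomy.  Each iteration matches every moving point to its nearest fixed
point (k-d tree), rejects pairs far beyond the median match distance, and
estimates the rigid transform that minimises the point-to-plane cost

    sum_i [ (R p_i + t - q_i) . n_i ]^2

where n_i is the fixed-surface normal at the matched point q_i.  The
rotation is linearised around the identity (small-angle assumption, valid
because the update per iteration is small) giving a 6x6 linear system; the
resulting axis-angle update is converted to an exact rotation matrix, so the
returned transform is always rigid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .exceptions import (
    DegenerateNormalsError,
    NonOverlappingCloudsError,
    RegistrationError,
)
from .surface_io import LabeledSurface, NormalField, estimate_normals

__all__ = [
    "RigidTransform",
    "IcpConfig",
    "IcpDiagnostics",
    "find_correspondences",
    "solve_point_to_plane",
    "icp_point_to_plane",
    "apply_transform",
    "initialize_transform",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform v -> R v + t (rotation in SO(3), mm units)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.ascontiguousarray(self.rotation, dtype=np.float64)
        t = np.ascontiguousarray(self.translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1 within 1e-9")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(matrix: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (re-orthonormalised)."""
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return RigidTransform(
            orthonormalize(matrix[:3, :3]), matrix[:3, 3].copy()
        )

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first, then ``self``)."""
        return RigidTransform(
            orthonormalize(self.rotation @ other.rotation),
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        return float(
            np.degrees(Rotation.from_matrix(self.rotation).magnitude())
        )

    def save(self, path) -> None:
        """Write as a plain-text row-major 4x4 homogeneous matrix (mm)."""
        np.savetxt(path, self.as_matrix(), fmt="%.17g")

    @staticmethod
    def load(path) -> "RigidTransform":
        return RigidTransform.from_matrix(np.loadtxt(path))


def orthonormalize(matrix: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto the closest proper rotation (polar
    decomposition via SVD)."""
    u, _, vt = np.linalg.svd(np.asarray(matrix, dtype=np.float64))
    R = u @ vt
    if np.linalg.det(R) < 0:
        u[:, -1] = -u[:, -1]
        R = u @ vt
    return R


@dataclass
class IcpConfig:
    """Iteration, convergence and correspondence controls for ICP.

    ``rejection_distance_factor`` discards matched pairs whose distance
    exceeds that multiple of the median match distance — robustness against
    partially mapped (EAM) anatomies.  ``init_strategy`` is used when no
    explicit initial transform is supplied: ``centroid`` translates the
    moving centroid onto the fixed one; ``centroid_pca`` additionally aligns
    principal axes (for anatomies in arbitrary frames).
    """

    max_iterations: int = 50
    rmse_rel_tolerance: float = 1e-4
    rejection_distance_factor: float = 3.0
    min_correspondences: int = 6
    init_strategy: str = "centroid"

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.rmse_rel_tolerance <= 0:
            raise ValueError("rmse_rel_tolerance must be > 0")
        if self.rejection_distance_factor <= 1:
            raise ValueError("rejection_distance_factor must be > 1")
        if self.init_strategy not in {"identity", "centroid", "centroid_pca"}:
            raise ValueError(
                "init_strategy must be identity, centroid or centroid_pca"
            )


@dataclass
class IcpDiagnostics:
    """Per-iteration record of an ICP run."""

    rmse_mm: list[float] = field(default_factory=list)
    correspondences_used: list[int] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False

    @property
    def final_rmse_mm(self) -> float:
        return self.rmse_mm[-1] if self.rmse_mm else float("nan")


def find_correspondences(
    moving_points: np.ndarray,
    fixed_points: np.ndarray | cKDTree,
    rejection_distance_factor: float = 3.0,
    min_correspondences: int = 6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-fixed-point match for every moving point, with median-based
    outlier rejection.

    Returns ``(moving_idx, fixed_idx, distances)`` for the surviving pairs.
    Pairs with distance > rejection_distance_factor x median distance are
    discarded.
    """
    moving_points = np.asarray(moving_points, dtype=np.float64)
    if len(moving_points) == 0:
        raise NonOverlappingCloudsError("moving cloud is empty")
    tree = (
        fixed_points
        if isinstance(fixed_points, cKDTree)
        else cKDTree(np.asarray(fixed_points, dtype=np.float64))
    )
    if tree.n == 0:
        raise NonOverlappingCloudsError("fixed cloud is empty")
    distances, fixed_idx = tree.query(moving_points)
    median = float(np.median(distances))
    keep = distances <= rejection_distance_factor * max(median, 1e-300)
    if median == 0.0:
        keep = np.ones(len(distances), dtype=bool)
    if int(keep.sum()) < min_correspondences:
        raise NonOverlappingCloudsError(
            f"only {int(keep.sum())} correspondences survived rejection "
            f"(minimum {min_correspondences}); clouds may not overlap"
        )
    moving_idx = np.flatnonzero(keep)
    return moving_idx, fixed_idx[keep], distances[keep]


def point_to_plane_cost(
    moving: np.ndarray,
    fixed: np.ndarray,
    normals: np.ndarray,
    transform: RigidTransform | None = None,
) -> float:
    """Sum of squared plane residuals sum_i [(R p_i + t - q_i) . n_i]^2."""
    p = moving if transform is None else transform.apply(moving)
    residuals = np.einsum("ij,ij->i", p - fixed, normals)
    return float(residuals @ residuals)


def solve_point_to_plane(
    moving: np.ndarray,
    fixed: np.ndarray,
    fixed_normals: np.ndarray,
) -> RigidTransform:
    """Point-to-plane solve for matched point sets.

    Gauss-Newton on the plane cost: each step linearises the rotation
    around the current estimate (small-angle update R ~ I + [w]_x, exact
    within one ICP step) and solves the resulting 6-parameter least-squares
    problem, with step halving as a safeguard, until the cost stops
    decreasing.  For pure-translation data the first step is already exact.
    The returned transform is rigid by construction and never costs more
    than the identity.

    Rank deficiency (e.g. all normals parallel) leaves some rigid degrees
    of freedom unconstrained; the minimum-norm solution (zero motion along
    them) is accepted only when it explains the residuals exactly,
    otherwise a :class:`DegenerateNormalsError` is raised.
    """
    p0 = np.asarray(moving, dtype=np.float64)
    q = np.asarray(fixed, dtype=np.float64)
    n = np.asarray(fixed_normals, dtype=np.float64)
    if len(p0) < 6:
        raise RegistrationError(
            f"need at least 6 correspondences, got {len(p0)}"
        )
    transform = RigidTransform.identity()
    cost = point_to_plane_cost(p0, q, n)
    for outer in range(50):
        p = transform.apply(p0)
        A = np.hstack([np.cross(p, n), n])  # (m, 6): [p x n, n]
        b = np.einsum("ij,ij->i", q - p, n)
        x, _, rank, _ = np.linalg.lstsq(A, b, rcond=1e-10)
        if outer == 0 and rank < 6:
            fit = float(np.sum((A @ x - b) ** 2))
            if fit > max(1e-12, 1e-10 * cost):
                raise DegenerateNormalsError(
                    "point-to-plane system is rank deficient (e.g. all "
                    "normals parallel): some rigid degrees of freedom are "
                    "unconstrained"
                )
        step = 1.0
        improved = False
        for _ in range(20):
            delta = RigidTransform(
                Rotation.from_rotvec(step * x[:3]).as_matrix(), step * x[3:]
            )
            candidate = delta @ transform
            new_cost = point_to_plane_cost(p0, q, n, candidate)
            if new_cost <= cost + 1e-15:
                improved = new_cost < cost - 1e-15 * max(1.0, cost)
                transform, cost = candidate, new_cost
                break
            step *= 0.5
        if not improved:
            break
    return transform


def initialize_transform(
    moving: np.ndarray,
    fixed: np.ndarray,
    strategy: str = "centroid",
) -> RigidTransform:
    """Initial alignment before iterating.

    ``centroid_pca`` aligns the principal axes of the two clouds; among the
    four proper rotations consistent with the (sign-ambiguous) axes it keeps
    the one with the lowest nearest-neighbour RMSE.
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if strategy == "identity":
        return RigidTransform.identity()
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    if strategy == "centroid":
        return RigidTransform(np.eye(3), cf - cm)
    if strategy != "centroid_pca":
        raise ValueError(f"unknown init strategy '{strategy}'")
    _, _, vm = np.linalg.svd(moving - cm, full_matrices=False)
    _, _, vf = np.linalg.svd(fixed - cf, full_matrices=False)
    tree = cKDTree(fixed)
    best: RigidTransform | None = None
    best_rmse = np.inf
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            signs = np.diag([s1, s2, s1 * s2])  # det +1 sign assignments
            R = vf.T @ signs @ vm
            if np.linalg.det(R) < 0:  # guard against reflective SVD bases
                R = vf.T @ (signs @ np.diag([1, 1, -1])) @ vm
            R = orthonormalize(R)
            candidate = RigidTransform(R, cf - R @ cm)
            d, _ = tree.query(candidate.apply(moving))
            rmse = float(np.sqrt(np.mean(d**2)))
            if rmse < best_rmse:
                best, best_rmse = candidate, rmse
    assert best is not None
    return best


def icp_point_to_plane(
    moving: LabeledSurface | np.ndarray,
    fixed: LabeledSurface | np.ndarray,
    fixed_normals: NormalField | np.ndarray | None = None,
    config: IcpConfig | None = None,
    initial: RigidTransform | None = None,
) -> tuple[RigidTransform, IcpDiagnostics]:
    """Iterative closest-point registration with a point-to-plane metric.

    Iterates correspondence search and the linearised solve until the
    relative change in point-to-plane RMSE drops below
    ``config.rmse_rel_tolerance`` or ``config.max_iterations`` is reached.
    A step that *raises* the re-matched RMSE is discarded and retried at
    half length (up to 8 halvings); when no damped step improves, the loop
    terminates.  The recorded RMSE sequence is therefore non-increasing.

    Returns the composed transform mapping the moving cloud into the fixed
    frame (including the initial transform) and per-iteration diagnostics.
    """
    config = config or IcpConfig()
    mv = moving.vertices if isinstance(moving, LabeledSurface) else np.asarray(moving, float)
    fx = fixed.vertices if isinstance(fixed, LabeledSurface) else np.asarray(fixed, float)
    if len(mv) == 0 or len(fx) == 0:
        raise RegistrationError("cannot register empty clouds")
    if fixed_normals is None:
        if not isinstance(fixed, LabeledSurface):
            raise ValueError("fixed_normals required for raw point arrays")
        fixed_normals = estimate_normals(fixed)
    normals = (
        fixed_normals.normals
        if isinstance(fixed_normals, NormalField)
        else np.asarray(fixed_normals, float)
    )
    if len(normals) != len(fx):
        raise ValueError("fixed_normals count must equal fixed vertex count")

    transform = initial if initial is not None else initialize_transform(
        mv, fx, config.init_strategy
    )
    tree = cKDTree(fx)
    diag = IcpDiagnostics()

    def evaluate(candidate: RigidTransform, iteration: int):
        points = candidate.apply(mv)
        try:
            midx, fidx, _ = find_correspondences(
                points,
                tree,
                config.rejection_distance_factor,
                config.min_correspondences,
            )
        except NonOverlappingCloudsError as exc:
            raise NonOverlappingCloudsError(
                f"iteration {iteration}: {exc}"
            ) from exc
        residuals = np.einsum(
            "ij,ij->i", points[midx] - fx[fidx], normals[fidx]
        )
        return float(np.sqrt(np.mean(residuals**2))), midx, fidx

    rmse, midx, fidx = evaluate(transform, 1)
    diag.rmse_mm.append(rmse)
    diag.correspondences_used.append(len(midx))
    diag.iterations_run = 1
    while diag.iterations_run < config.max_iterations:
        if rmse < 1e-9:
            diag.converged = True
            break
        iteration = diag.iterations_run + 1
        points = transform.apply(mv)
        try:
            delta = solve_point_to_plane(points[midx], fx[fidx], normals[fidx])
        except RegistrationError as exc:
            raise type(exc)(f"iteration {iteration}: {exc}") from exc
        rotvec = Rotation.from_matrix(delta.rotation).as_rotvec()
        # damped acceptance: a full step whose re-matched RMSE rises is
        # discarded and retried at half length, keeping the accepted RMSE
        # sequence non-increasing without abandoning a descending run
        accepted = None
        step = 1.0
        for _ in range(8):
            scaled = RigidTransform(
                Rotation.from_rotvec(step * rotvec).as_matrix(),
                step * delta.translation,
            )
            candidate = scaled @ transform
            cand_rmse, cand_m, cand_f = evaluate(candidate, iteration)
            if cand_rmse <= diag.rmse_mm[-1] + 1e-9:
                accepted = (candidate, cand_rmse, cand_m, cand_f)
                break
            step *= 0.5
        if accepted is None:
            diag.converged = True
            break
        transform, rmse, midx, fidx = accepted
        diag.rmse_mm.append(rmse)
        diag.correspondences_used.append(len(midx))
        diag.iterations_run += 1
        prev_rmse = diag.rmse_mm[-2]
        if abs(prev_rmse - rmse) <= config.rmse_rel_tolerance * max(
            prev_rmse, 1e-300
        ):
            diag.converged = True
            break
    else:
        if rmse < 1e-9:
            diag.converged = True
    return transform, diag


def apply_transform(
    surface: LabeledSurface, transform: RigidTransform
) -> LabeledSurface:
    """Return a copy of ``surface`` with vertices mapped v -> R v + t.

    Faces and labels are carried over unchanged; being rigid, the map
    preserves all pairwise distances.
    """
    out = surface.copy()
    out.vertices = transform.apply(surface.vertices)
    return out
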