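"""Two-stage alignment of imaging anatomies with EAM anatomies.

Stage 1 registers the *entire* segmentations — the pulmonary veins, the
appendage and the mitral annulus are the most distinctive landmarks and
drive the registration into the right pose.  Stage 2 then re-runs the ICP
on copies with those distinctive structures excluded, capped at a small
number of iterations (3 by default) and initialised at the stage-1 result,
so that it can only *refine* the alignment of the true atrial-body surface
without being pulled away by structures that are segmented differently in
the two modalities.

The result is flagged pass/fail by an automatic surrogate for a visual
check: the body-surface median residual must stay below a threshold,
stage 1 must have converged, and stage 2 must not have degraded the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AtrialignError, RegistrationError
from .metrics import DEFAULT_THRESHOLDS_MM, DistanceSummary, residual_distances
from .registration import (
    IcpConfig,
    IcpDiagnostics,
    RigidTransform,
    apply_transform,
    icp_point_to_plane,
    initialize_transform,
)
from .remeshing import (
    RemeshConfig,
    _spacing_distribution,
    isotropic_remesh,
    isotropy_cv,
)
from .surface_io import (
    LANDMARK_LABELS,
    AnatomicalLabel,
    LabeledSurface,
    estimate_normals,
)

__all__ = [
    "PipelineConfig",
    "AlignmentResult",
    "align_two_stage",
    "flag_alignment",
]


def _default_stage1() -> IcpConfig:
    return IcpConfig()


def _default_stage2() -> IcpConfig:
    return IcpConfig(max_iterations=3)


@dataclass
class PipelineConfig:
    """Controls for the two-stage alignment.

    ``stage2_excluded_labels`` defaults to all distinctive landmarks
    (4 PVs, appendage, annulus) — the same set excluded from the residual
    metric.  ``remesh_mode`` selects which inputs are made isotropic before
    stage 1: ``'trigger'`` remeshes any input whose spacing CV exceeds
    ``remesh_cv_trigger``, ``'imaging'`` remeshes only the imaging side,
    ``'off'`` disables remeshing.
    """

    stage1: IcpConfig = field(default_factory=_default_stage1)
    stage2: IcpConfig = field(default_factory=_default_stage2)
    stage2_excluded_labels: frozenset = LANDMARK_LABELS
    stage2_max_iterations: int = 3
    fail_median_mm: float = 5.0
    remesh: RemeshConfig = field(default_factory=RemeshConfig)
    remesh_mode: str = "trigger"
    remesh_cv_trigger: float = 0.4
    normals_k: int = 12
    metric_thresholds_mm: tuple = DEFAULT_THRESHOLDS_MM

    def __post_init__(self) -> None:
        if self.stage2_max_iterations < 1:
            raise ValueError("stage2_max_iterations must be >= 1")
        allowed = {int(label) for label in AnatomicalLabel} - {
            int(AnatomicalLabel.BODY)
        }
        excluded = {int(e) for e in self.stage2_excluded_labels}
        if not excluded.issubset(allowed):
            raise ValueError(
                "stage2_excluded_labels must be a subset of the non-body "
                "anatomical labels"
            )
        self.stage2_excluded_labels = frozenset(
            AnatomicalLabel(e) for e in excluded
        )
        if self.remesh_mode not in {"trigger", "imaging", "off"}:
            raise ValueError("remesh_mode must be trigger, imaging or off")


@dataclass
class AlignmentResult:
    """Outcome of a two-stage alignment.

    ``composed_transform`` maps the original imaging anatomy into the EAM
    frame and always equals ``stage2_transform ∘ stage1_transform``.
    """

    stage1_transform: RigidTransform
    stage2_transform: RigidTransform
    composed_transform: RigidTransform
    stage1_diagnostics: IcpDiagnostics
    stage2_diagnostics: IcpDiagnostics
    residuals: DistanceSummary
    passed: bool
    fail_reason: str | None = None

    def __post_init__(self) -> None:
        expected = self.stage2_transform @ self.stage1_transform
        if not (
            np.allclose(
                expected.rotation, self.composed_transform.rotation, atol=1e-9
            )
            and np.allclose(
                expected.translation,
                self.composed_transform.translation,
                atol=1e-9,
            )
        ):
            raise ValueError(
                "composed_transform must equal stage2 ∘ stage1"
            )


def flag_alignment(
    stage1_diag: IcpDiagnostics,
    stage2_diag: IcpDiagnostics,
    residuals: DistanceSummary,
    fail_median_mm: float = 5.0,
) -> tuple[bool, str | None]:
    """Automatic pass/fail surrogate for a visual alignment check.

    Fails when (first failing check names the reason):

    1. the body-surface median residual exceeds ``fail_median_mm``;
    2. stage 1 never converged;
    3. stage 2 ended with a point-to-plane RMSE more than 20% above the
       stage-1 final RMSE (refinement made things worse).
    """
    if residuals.median_mm > fail_median_mm:
        return False, "median_exceeds_threshold"
    if not stage1_diag.converged:
        return False, "stage1_not_converged"
    s1 = stage1_diag.final_rmse_mm
    s2 = stage2_diag.final_rmse_mm
    if np.isfinite(s1) and np.isfinite(s2) and s1 > 1e-6 and s2 > 1.2 * s1:
        return False, "stage2_rmse_regression"
    return True, None


def _maybe_remesh(
    surface: LabeledSurface, config: PipelineConfig, is_imaging: bool
) -> LabeledSurface:
    if config.remesh_mode == "off":
        return surface
    if config.remesh_mode == "imaging" and not is_imaging:
        return surface
    if config.remesh_mode == "trigger":
        if isotropy_cv(surface) <= config.remesh_cv_trigger:
            return surface
        if surface.faces is None or not len(surface.faces):
            # resampling can only thin a point cloud, never densify it:
            # a cloud already sparser than the target spacing is left as-is
            median_nn = float(np.median(_spacing_distribution(surface)))
            if median_nn >= config.remesh.target_spacing:
                return surface
    return isotropic_remesh(surface, config.remesh)


def align_two_stage(
    imaging: LabeledSurface,
    eam: LabeledSurface,
    config: PipelineConfig | None = None,
) -> AlignmentResult:
    """Run the full two-stage alignment of an imaging anatomy onto an EAM
    anatomy and compute residual-distance quality metrics.

    The imaging anatomy is the moving cloud; the EAM anatomy is fixed and
    supplies the plane normals.  Stage 2 excludes
    ``config.stage2_excluded_labels`` from the imaging side (and from the
    EAM side too when it carries labels) and is initialised exactly at the
    stage-1 result.
    """
    config = config or PipelineConfig()
    if imaging.n_vertices == 0 or eam.n_vertices == 0:
        raise AtrialignError("cannot align empty surfaces")

    moving = _maybe_remesh(imaging, config, is_imaging=True)
    fixed = _maybe_remesh(eam, config, is_imaging=False)
    fixed_normals = estimate_normals(fixed, config.normals_k)

    initial = initialize_transform(
        moving.vertices, fixed.vertices, config.stage1.init_strategy
    )
    try:
        stage1_T, stage1_diag = icp_point_to_plane(
            moving, fixed, fixed_normals, config.stage1, initial
        )
    except RegistrationError as exc:
        raise type(exc)(f"stage 1: {exc}") from exc

    excluded = config.stage2_excluded_labels
    moving2 = moving.without_labels(excluded)
    if moving2.n_vertices == 0:
        raise AtrialignError(
            "imaging surface empty after stage-2 label exclusion"
        )
    if np.any(fixed.labels != int(AnatomicalLabel.BODY)):
        fixed2 = fixed.without_labels(excluded)
        if fixed2.n_vertices == 0:
            raise AtrialignError(
                "EAM surface empty after stage-2 label exclusion"
            )
    else:
        fixed2 = fixed  # unlabeled EAM: nothing to exclude
    fixed2_normals = (
        estimate_normals(fixed2, config.normals_k)
        if fixed2 is not fixed
        else fixed_normals
    )
    stage2_cfg = IcpConfig(
        max_iterations=config.stage2_max_iterations,
        rmse_rel_tolerance=config.stage2.rmse_rel_tolerance,
        rejection_distance_factor=config.stage2.rejection_distance_factor,
        min_correspondences=config.stage2.min_correspondences,
        init_strategy=config.stage2.init_strategy,
    )
    try:
        total_T, stage2_diag = icp_point_to_plane(
            moving2, fixed2, fixed2_normals, stage2_cfg, stage1_T
        )
    except RegistrationError as exc:
        raise type(exc)(f"stage 2: {exc}") from exc
    stage2_T = total_T @ stage1_T.inverse()

    aligned = apply_transform(moving, total_T)
    residuals = residual_distances(
        aligned,
        fixed,
        excluded_labels=excluded,
        thresholds_mm=config.metric_thresholds_mm,
    )
    passed, reason = flag_alignment(
        stage1_diag, stage2_diag, residuals, config.fail_median_mm
    )
    return AlignmentResult(
        stage1_transform=stage1_T,
        stage2_transform=stage2_T,
        composed_transform=total_T,
        stage1_diagnostics=stage1_diag,
        stage2_diagnostics=stage2_diag,
        residuals=residuals,
        passed=passed,
        fail_reason=reason,
    )
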