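"""YAML run configuration.

A single YAML document configures the whole pipeline.  Keys mirror the
module structure::

    remesh:
      target_spacing_mm: 1.5
      cv_threshold: 0.3
      max_deviation_mm: 0.5
    icp:                  # stage-1 controls
      max_iterations: 50
      tolerance: 1.0e-4
      rejection_factor: 3.0
      init: centroid
    pipeline:
      stage2_max_iterations: 3
      stage2_excluded_labels: [LSPV, LIPV, RSPV, RIPV, LAA, MV_ANNULUS]
      fail_median_mm: 5.0
      remesh_mode: trigger
    metrics:
      thresholds_mm: [2.5, 5.0]
    phantom:
      target_spacing_mm: 2.0

Unknown keys are rejected, so typos fail loudly instead of silently using
defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .phantom import PhantomParams
from .pipeline import PipelineConfig
from .registration import IcpConfig
from .remeshing import RemeshConfig
from .surface_io import AnatomicalLabel

__all__ = ["RunConfig", "load_config"]

_REMESH_KEYS = {
    "target_spacing_mm": "target_spacing",
    "cv_threshold": "isotropy_cv_threshold",
    "max_deviation_mm": "max_surface_deviation",
}
_ICP_KEYS = {
    "max_iterations": "max_iterations",
    "tolerance": "rmse_rel_tolerance",
    "rejection_factor": "rejection_distance_factor",
    "min_correspondences": "min_correspondences",
    "init": "init_strategy",
}
_PIPELINE_KEYS = {
    "stage2_max_iterations",
    "stage2_excluded_labels",
    "fail_median_mm",
    "remesh_mode",
    "remesh_cv_trigger",
    "normals_k",
}
_PHANTOM_KEYS = {
    "body_semi_axes_mm": "body_semi_axes",
    "body_irregularity": "body_irregularity",
    "pv_radius_mm": "pv_radius",
    "pv_length_mm": "pv_length",
    "laa_length_mm": "laa_length",
    "laa_radius_mm": "laa_radius",
    "annulus_radius_mm": "annulus_radius",
    "target_spacing_mm": "target_spacing",
    "seed": "seed",
}


def _check_keys(section: str, mapping: dict, allowed) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}': {sorted(unknown)} "
            f"(allowed: {sorted(allowed)})"
        )


def _parse_labels(tokens) -> frozenset:
    labels = set()
    for token in tokens:
        try:
            labels.add(AnatomicalLabel[str(token).upper()])
        except KeyError as exc:
            raise ConfigError(f"unknown anatomical label '{token}'") from exc
    return frozenset(labels)


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    log_level: str = "INFO"
    output_dir: str = "."

    def to_yaml(self) -> str:
        """Serialise the resolved configuration back to a YAML document
        that :func:`load_config` accepts."""
        pipe = self.pipeline

        def icp_doc(icp: IcpConfig) -> dict:
            return {
                "max_iterations": icp.max_iterations,
                "tolerance": icp.rmse_rel_tolerance,
                "rejection_factor": icp.rejection_distance_factor,
                "min_correspondences": icp.min_correspondences,
                "init": icp.init_strategy,
            }

        document = {
            "remesh": {
                "target_spacing_mm": pipe.remesh.target_spacing,
                "cv_threshold": pipe.remesh.isotropy_cv_threshold,
                "max_deviation_mm": pipe.remesh.max_surface_deviation,
            },
            "icp": icp_doc(pipe.stage1),
            "icp_stage2": icp_doc(pipe.stage2),
            "pipeline": {
                "stage2_max_iterations": pipe.stage2_max_iterations,
                "stage2_excluded_labels": sorted(
                    label.name for label in pipe.stage2_excluded_labels
                ),
                "fail_median_mm": pipe.fail_median_mm,
                "remesh_mode": pipe.remesh_mode,
                "remesh_cv_trigger": pipe.remesh_cv_trigger,
                "normals_k": pipe.normals_k,
            },
            "metrics": {
                "thresholds_mm": list(pipe.metric_thresholds_mm),
            },
            "phantom": {
                "body_semi_axes_mm": list(self.phantom.body_semi_axes),
                "body_irregularity": self.phantom.body_irregularity,
                "pv_radius_mm": self.phantom.pv_radius,
                "pv_length_mm": self.phantom.pv_length,
                "laa_length_mm": self.phantom.laa_length,
                "laa_radius_mm": self.phantom.laa_radius,
                "annulus_radius_mm": self.phantom.annulus_radius,
                "target_spacing_mm": self.phantom.target_spacing,
                "seed": self.phantom.seed,
            },
            "log_level": self.log_level,
            "output_dir": self.output_dir,
        }
        return yaml.safe_dump(document, sort_keys=False)

    def config_hash(self) -> str:
        """Stable hash of the resolved configuration (for provenance)."""
        blob = repr(
            (
                self.pipeline,
                self.phantom,
                self.log_level,
            )
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file, applying defaults for
    everything unspecified.  ``overrides`` (section -> key -> value) take
    precedence over the file."""
    document: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config document must be a YAML mapping")
        document = loaded
    for section, values in (overrides or {}).items():
        document.setdefault(section, {}).update(values)
    _check_keys(
        "config",
        document,
        {"remesh", "icp", "icp_stage2", "pipeline", "metrics", "phantom",
         "log_level", "output_dir"},
    )

    remesh_doc = document.get("remesh", {})
    _check_keys("remesh", remesh_doc, _REMESH_KEYS)
    remesh = RemeshConfig(
        **{_REMESH_KEYS[k]: v for k, v in remesh_doc.items()}
    )

    def icp_from(section: str, defaults: IcpConfig) -> IcpConfig:
        doc = document.get(section, {})
        _check_keys(section, doc, _ICP_KEYS)
        kwargs = {
            "max_iterations": defaults.max_iterations,
            "rmse_rel_tolerance": defaults.rmse_rel_tolerance,
            "rejection_distance_factor": defaults.rejection_distance_factor,
            "min_correspondences": defaults.min_correspondences,
            "init_strategy": defaults.init_strategy,
        }
        kwargs.update({_ICP_KEYS[k]: v for k, v in doc.items()})
        try:
            return IcpConfig(**kwargs)
        except ValueError as exc:
            raise ConfigError(f"{section}: {exc}") from exc

    stage1 = icp_from("icp", IcpConfig())
    stage2 = icp_from("icp_stage2", IcpConfig(max_iterations=3))

    pipe_doc = dict(document.get("pipeline", {}))
    _check_keys("pipeline", pipe_doc, _PIPELINE_KEYS)
    if "stage2_excluded_labels" in pipe_doc:
        pipe_doc["stage2_excluded_labels"] = _parse_labels(
            pipe_doc["stage2_excluded_labels"]
        )
    metrics_doc = document.get("metrics", {})
    _check_keys("metrics", metrics_doc, {"thresholds_mm"})
    thresholds = tuple(
        float(t) for t in metrics_doc.get("thresholds_mm", (2.5, 5.0))
    )
    try:
        pipeline = PipelineConfig(
            stage1=stage1,
            stage2=stage2,
            remesh=remesh,
            metric_thresholds_mm=thresholds,
            **pipe_doc,
        )
    except ValueError as exc:
        raise ConfigError(f"pipeline: {exc}") from exc

    phantom_doc = document.get("phantom", {})
    _check_keys("phantom", phantom_doc, _PHANTOM_KEYS)
    kwargs = {_PHANTOM_KEYS[k]: v for k, v in phantom_doc.items()}
    if "body_semi_axes" in kwargs:
        kwargs["body_semi_axes"] = tuple(
            float(x) for x in kwargs["body_semi_axes"]
        )
    phantom = PhantomParams(**kwargs)

    return RunConfig(
        pipeline=pipeline,
        phantom=phantom,
        log_level=str(document.get("log_level", "INFO")),
        output_dir=str(document.get("output_dir", ".")),
    )
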