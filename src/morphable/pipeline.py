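"""End-to-end model-construction pipeline.

Orchestrates the five stages over a directory of raw scans: (1) automatic
landmarking, (2) non-rigid ICP dense correspondence against the template,
(3) initial global PCA, (4) chi-square pruning of failed registrations,
(5) final model builds (global and, when demographics are available,
bespoke per-group), plus optional evaluation curves.

Per-subject failures (unreadable meshes, landmarking or registration
errors) are recorded in the manifest with a reason code and skipped —
only fewer than 3 surviving subjects is fatal.  Stage-2 registrations are
cached on disk keyed by a content hash of the mesh bytes, landmarks and
registration config, so reruns resume; with fixed seeds and the
deterministic eigenvector sign convention two complete runs produce
byte-identical model archives.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .align import generalized_procrustes
from .evaluation import compactness_curve, generalization_curve
from .fixtures import ProjectingDetector
from .landmarking import auto_landmark, load_detector
from .mesh import DemographicRecord, LandmarkSet, TriangleMesh
from .models import build_pca, default_bespoke_rules, save_model
from .nicp import NICPConfig, nicp_register
from .pruning import prune_and_rebuild, write_report_csv
from .rendering import default_camera_rig

log = logging.getLogger(__name__)

MANIFEST_SCHEMA_VERSION = 1


def projecting_detector_factory(context: dict) -> ProjectingDetector:
    """Built-in detector plug-in: projects the subject's landmark JSON
    file (sitting next to its mesh) into each rendered view.  This is the
    seam synthetic runs use; real deployments point ``detector`` at a
    trained 2D localizer instead."""
    lm_path = Path(context["mesh_path"]).with_suffix(".json")
    return ProjectingDetector(mio.read_landmarks(lm_path))


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    input_dir: str
    output_dir: str
    template_path: str | None = None      # None -> built-in synthetic face
    template_landmarks_path: str | None = None
    demographics_csv: str | None = None
    landmark_source: str = "detector"     # {"detector", "files"}
    detector: str = "morphable.pipeline:projecting_detector_factory"
    n_views: int = 5
    image_size: int = 256
    nicp: NICPConfig = field(default_factory=NICPConfig)
    p_f: float = 0.99
    variance_to_retain: float = 0.995
    build_bespoke: bool = False
    evaluate_compactness: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input_dir {self.input_dir} missing")
        for p in (self.template_path, self.template_landmarks_path,
                  self.demographics_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.template_path and not self.template_landmarks_path:
            raise ValueError("template_path requires "
                             "template_landmarks_path")
        if self.landmark_source not in ("detector", "files"):
            raise ValueError("landmark_source must be detector or files")
        if not 0 < self.p_f < 1:
            raise ValueError("p_f must be in (0, 1)")
        if not 0 < self.variance_to_retain <= 1:
            raise ValueError("variance_to_retain must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        nicp = NICPConfig(**doc.pop("nicp", {}))
        cfg = cls(nicp=nicp, **doc)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nicp"] = asdict(self.nicp)
        return d


def _load_template(config: PipelineConfig
                   ) -> tuple[TriangleMesh, LandmarkSet]:
    if config.template_path is None:
        from .fixtures import make_template
        return make_template(resolution=1)
    mesh = mio.read_mesh(config.template_path)
    lms = mio.read_landmarks(config.template_landmarks_path)
    if lms.template_indices is None:
        raise ValueError("template landmarks must carry template_indices")
    return mesh, lms


def _load_demographics(path: str | None) -> dict[str, DemographicRecord]:
    if path is None:
        return {}
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["subject_id"]] = DemographicRecord(
                subject_id=row["subject_id"], age=float(row["age"]),
                gender=row["gender"], ethnicity=row["ethnicity"])
    return out


def _content_hash(*parts: bytes) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p)
        h.update(b"\x00")
    return h.hexdigest()[:24]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the five pipeline stages; returns the output directory.

    Writes corresponded meshes, the pruning report, HDF5 model archives,
    evaluation curves and a JSON manifest describing per-subject fates.
    """
    config.validate()
    out = Path(config.output_dir)
    (out / "corresponded").mkdir(parents=True, exist_ok=True)
    (out / "cache").mkdir(exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)

    template, template_lms = _load_template(config)
    demographics = _load_demographics(config.demographics_csv)
    mesh_paths = sorted(Path(config.input_dir).glob("*.ply")) + sorted(
        Path(config.input_dir).glob("*.obj"))
    nicp_blob = json.dumps(asdict(config.nicp), sort_keys=True).encode()
    records: list[dict] = []
    corresponded: list[TriangleMesh] = []
    ids: list[str] = []

    for path in mesh_paths:
        sid = path.stem
        rec: dict = {"subject_id": sid, "mesh": str(path)}
        t0 = time.monotonic()
        try:
            mesh = mio.read_mesh(path)
        except Exception as e:
            rec.update(status="failed", stage="read", reason=str(e))
            records.append(rec)
            log.warning("%s: unreadable mesh skipped (%s)", sid, e)
            continue
        try:
            if config.landmark_source == "files":
                lms = mio.read_landmarks(path.with_suffix(".json"))
            else:
                detector = load_detector(
                    config.detector,
                    context={"subject_id": sid, "mesh_path": str(path),
                             "input_dir": config.input_dir})
                cameras = default_camera_rig(
                    mesh, image_shape=(config.image_size, config.image_size),
                    yaw_angles_deg=tuple(np.linspace(
                        -60, 60, config.n_views)))
                lms = auto_landmark(mesh, cameras, detector)
        except Exception as e:
            rec.update(status="failed", stage="landmarking", reason=str(e))
            records.append(rec)
            log.warning("%s: landmarking failed (%s)", sid, e)
            continue
        key = _content_hash(path.read_bytes(), lms.points.tobytes(),
                            lms.valid_mask.tobytes(), nicp_blob,
                            template.points.tobytes())
        cached = out / "cache" / f"{key}.ply"
        try:
            if cached.exists():
                deformed = mio.read_mesh(cached)
                rec["cached"] = True
            else:
                result = nicp_register(template, mesh, template_lms, lms,
                                       config.nicp)
                mio.write_mesh(result.deformed_template, cached)
                # the disk artifact (float32 PLY) is canonical, so fresh
                # and resumed runs build bit-identical models
                deformed = mio.read_mesh(cached)
                rec["mean_surface_distance_mm"] = float(
                    result.per_vertex_distance.mean())
        except Exception as e:
            rec.update(status="failed", stage="registration", reason=str(e))
            records.append(rec)
            log.warning("%s: registration failed (%s)", sid, e)
            continue
        mio.write_mesh(deformed, out / "corresponded" / f"{sid}.ply")
        rec.update(status="corresponded",
                   seconds=round(time.monotonic() - t0, 3))
        records.append(rec)
        corresponded.append(deformed)
        ids.append(sid)

    if len(corresponded) < 3:
        raise RuntimeError(
            f"only {len(corresponded)} of {len(mesh_paths)} subjects "
            "survived to modelling; need >= 3")

    # similarity normalization, then the two-pass build with pruning
    aligned, _ = generalized_procrustes(corresponded)
    final_model, report = prune_and_rebuild(
        aligned, subject_ids=ids, p_f=config.p_f,
        variance_to_retain=config.variance_to_retain)
    write_report_csv(report, out / "pruning_report.csv")
    with open(out / "pruning_summary.json", "w") as f:
        json.dump(report.summary(), f, indent=1)
    for rec in records:
        if rec.get("status") == "corresponded":
            rec["pruned"] = rec["subject_id"] in report.flagged
    save_model(final_model, out / "model_global.h5")

    survivors = [m for m, sid in zip(aligned, ids)
                 if sid not in report.flagged]
    surv_ids = [sid for sid in ids if sid not in report.flagged]
    models = {"global": final_model}
    if config.build_bespoke and demographics:
        groups: dict[str, list[TriangleMesh]] = {}
        rules = default_bespoke_rules(
            binned_ethnicities=(), plain_ethnicities=sorted(
                {demographics[s].ethnicity for s in surv_ids
                 if s in demographics}))
        for m, sid in zip(survivors, surv_ids):
            if sid not in demographics:
                continue
            key = next((k for p, k in rules if p(demographics[sid])),
                       "global")
            groups.setdefault(key, []).append(m)
        for key, meshes in groups.items():
            if len(meshes) >= 3:
                models[key] = build_pca(
                    [m.as_vector() for m in meshes], final_model.trilist,
                    variance_to_retain=config.variance_to_retain)
                save_model(models[key], out / "model_bespoke.h5", key=key,
                           mode="a" if (out / "model_bespoke.h5").exists()
                           else "w")

    if config.evaluate_compactness:
        compactness_curve(final_model).to_csv(out / "compactness.csv")

    manifest = {"schema_version": MANIFEST_SCHEMA_VERSION,
                "config": config.to_dict(),
                "n_attempted": len(mesh_paths),
                "n_corresponded": len(corresponded),
                "n_pruned": int(report.flagged_mask.sum()),
                "n_in_final_model": len(survivors),
                "flagged": report.flagged,
                "models": sorted(models),
                "subjects": records}
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    logging.getLogger().removeHandler(fh)
    fh.close()
    return out


def manifest_report(output_dir) -> str:
    """Human-readable summary of a (possibly partial) run directory."""
    out = Path(output_dir)
    path = out / "manifest.json"
    if not path.exists():
        return f"{out}: no manifest — 0 subjects processed"
    with open(path) as f:
        man = json.load(f)
    lines = [f"pipeline run in {out}",
             f"  attempted:     {man['n_attempted']}",
             f"  corresponded:  {man['n_corresponded']}",
             f"  pruned:        {man['n_pruned']} "
             f"({', '.join(man['flagged']) or 'none'})",
             f"  final model:   {man['n_in_final_model']} subjects",
             f"  models built:  {', '.join(man['models'])}"]
    failures = [r for r in man["subjects"] if r.get("status") == "failed"]
    if failures:
        lines.append("  failures:")
        for r in failures:
            lines.append(f"    {r['subject_id']}: {r['stage']} — "
                         f"{r['reason']}")
    timed = [r.get("seconds") for r in man["subjects"] if "seconds" in r]
    if timed:
        lines.append(f"  median per-subject time: "
                     f"{float(np.median(timed)):.2f} s")
    return "\n".join(lines)
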