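"""Readers/writers and run configuration.

Volumes travel as MetaImage (.mha) or NIfTI (.nii/.nii.gz) with voxel
spacing honored. Contour stacks use a project-defined YAML schema (no
community standard exists for per-slice vessel contours):

.. code-block:: yaml

    bifurcation_z: 15.8      # mm
    isd: 2.0                 # mm
    slices:
      - z: 13.8
        vessel: CCA
        mab: [[x_mm, y_mm], ...]
        lib: [[x_mm, y_mm], ...]

Invariants (closed simple CCW polygons, LIB inside MAB, positive ISD) are
validated on read by the container constructors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Dict

import numpy as np
import SimpleITK as sitk
import yaml

from .geometry import Contour, ContourStack, Volume3DUS

log = logging.getLogger(__name__)

VOLUME_EXTENSIONS = (".mha", ".nii", ".nii.gz")


def _check_volume_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(e) for e in VOLUME_EXTENSIONS):
        raise ValueError(
            f"unsupported volume extension: {path.name} "
            f"(expected one of {VOLUME_EXTENSIONS})")


def write_volume(volume: Volume3DUS, path: str | Path) -> Path:
    path = Path(path)
    _check_volume_path(path)
    img = sitk.GetImageFromArray(np.asarray(volume.voxels, dtype=np.float32))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


def read_volume(path: str | Path) -> Volume3DUS:
    path = Path(path)
    _check_volume_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    voxels = sitk.GetArrayFromImage(img)  # (z, y, x)
    return Volume3DUS(voxels=voxels,
                      spacing=tuple(float(s) for s in img.GetSpacing()),
                      origin=tuple(float(o) for o in img.GetOrigin()))


def write_contours(stack: ContourStack, path: str | Path) -> Path:
    path = Path(path)
    doc: Dict[str, Any] = {
        "bifurcation_z": float(stack.bifurcation_z),
        "isd": float(stack.isd),
        "slices": [],
    }
    for z, (mab, lib) in stack.contours.items():
        doc["slices"].append({
            "z": float(z),
            "vessel": stack.vessel_of(z),
            "mab": [[float(x), float(y)] for x, y in mab.points],
            "lib": [[float(x), float(y)] for x, y in lib.points],
        })
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(doc, sort_keys=False,
                                   default_flow_style=None))
    return path


def read_contours(path: str | Path) -> ContourStack:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    try:
        contours = {}
        for sl in doc["slices"]:
            z = float(sl["z"])
            vessel = sl.get("vessel", "CCA")
            mab = Contour(points=np.asarray(sl["mab"], dtype=float), z=z,
                          boundary_kind="MAB", vessel=vessel)
            lib = Contour(points=np.asarray(sl["lib"], dtype=float), z=z,
                          boundary_kind="LIB", vessel=vessel)
            contours[z] = (mab, lib)
        return ContourStack(contours=contours,
                            bifurcation_z=float(doc["bifurcation_z"]),
                            isd=float(doc["isd"]))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed contour file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Serializable run configuration embedded in output artifacts."""
    seed: int = 0
    phantom: Dict[str, Any] = dataclasses.field(default_factory=dict)
    observer: Dict[str, Any] = dataclasses.field(default_factory=dict)
    train: Dict[str, Any] = dataclasses.field(default_factory=dict)
    metrics: Dict[str, Any] = dataclasses.field(default_factory=dict)
    paths: Dict[str, str] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in doc.items() if k in known})
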