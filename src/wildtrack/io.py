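"""MOTChallenge-dialect file I/O, embedding sidecars, and run configuration.

Detection and ground-truth files are plain comma-separated text, one line per
box, in the MOT16 dialect::

    frame, id, bb_left, bb_top, bb_width, bb_height, conf[, x, y, z]

Coordinates are 1-based pixels with boxes closed on left/top; all internal
geometry works on ``(cx, cy, w, h)`` floats, converted only here at the
boundary.  Embeddings have no column in MOT16, so they travel in a sidecar
file keyed by ``(frame, ordinal-within-frame)``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import yaml

__all__ = [
    "BoundingBox",
    "Detection",
    "GroundTruthEntry",
    "ResultRecord",
    "RunConfig",
    "MotFileError",
    "read_mot_file",
    "write_result_file",
    "read_embeddings",
    "write_embeddings",
    "attach_embeddings",
    "load_config",
]

# chi-square 0.95 quantile at 4 degrees of freedom: the standard cascade-
# matching gate on the squared Mahalanobis distance of a 4-d box measurement
CHI2_95_DOF4 = 9.4877


class MotFileError(ValueError):
    """A MOT-dialect file line could not be parsed."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in MOT pixel convention (1-based left/top corner)."""

    left: float
    top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"box width/height must be positive, got {self.width}x{self.height}"
            )

    @property
    def center(self) -> tuple[float, float]:
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height

    def to_cxcyah(self) -> np.ndarray:
        """Convert to (center_x, center_y, aspect=w/h, height) measurement."""
        cx, cy = self.center
        return np.array([cx, cy, self.width / self.height, self.height])

    @staticmethod
    def from_cxcyah(v: np.ndarray) -> "BoundingBox":
        cx, cy, a, h = float(v[0]), float(v[1]), float(v[2]), float(v[3])
        w = a * h
        return BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h)


@dataclass(frozen=True)
class Detection:
    """One detector candidate in one frame, optionally carrying a unit-norm
    appearance embedding."""

    frame: int
    box: BoundingBox
    confidence: float = 1.0
    embedding: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError(f"frame index must be >= 1, got {self.frame}")
        if self.embedding is not None:
            norm = float(np.linalg.norm(self.embedding))
            if abs(norm - 1.0) > 1e-6:
                raise ValueError(f"embedding must be unit-norm, |e| = {norm}")


@dataclass(frozen=True)
class GroundTruthEntry:
    frame: int
    identity: int
    box: BoundingBox


@dataclass(frozen=True)
class ResultRecord:
    """One output line of the tracker: a confirmed identity in a frame."""

    frame: int
    identity: int
    box: BoundingBox
    source: str = "detected"  # "detected" | "reconstructed"


@dataclass
class RunConfig:
    """All tracker/metric tunables with their defaults.

    The appearance gate is a cosine *distance* (1 - cos similarity), the
    Mahalanobis gate a squared distance, the center gate a fraction of the
    image diagonal, and the IoU gate a (1 - IoU) distance.
    """

    embedding_dim: int = 128
    appearance_gate: float = 0.2
    mahalanobis_gate: float = CHI2_95_DOF4
    center_gate: float = 0.05
    iou_gate: float = 0.7
    max_age: int = 30
    n_init: int = 3
    gallery_budget: int = 100
    central_margin: float = 0.1
    reconstruction_cap: int = 5       # consecutive-frame cap on reconstruction
    metric_iou_threshold: float = 0.5
    image_width: int = 640
    image_height: int = 480
    seed: int = 0
    # ablation toggles
    use_center_stage: bool = True
    use_iou_stage: bool = True
    # reconstructed box: copy of the last box (default) or Kalman extrapolation
    reconstruct_with_prediction: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.central_margin < 0.5):
            raise ValueError("central_margin must lie in (0, 0.5)")
        if self.reconstruction_cap < 0:
            raise ValueError("reconstruction_cap must be >= 0")
        for name in ("appearance_gate", "mahalanobis_gate", "center_gate", "iou_gate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def image_diagonal(self) -> float:
        return math.hypot(self.image_width, self.image_height)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a RunConfig from a YAML key-value file; kwargs override the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw.update(overrides)
    return RunConfig(**raw)


def _parse_line(line: str, lineno: int, kind: str):
    fields = [f.strip() for f in line.split(",")]
    if len(fields) < 7:
        raise MotFileError(f"line {lineno}: expected >= 7 comma-separated fields, got {len(fields)}")
    try:
        frame = int(float(fields[0]))
        ident = int(float(fields[1]))
        left, top, w, h = (float(f) for f in fields[2:6])
        conf = float(fields[6])
    except ValueError as exc:
        raise MotFileError(f"line {lineno}: non-numeric field ({exc})") from None
    if w <= 0 or h <= 0:
        raise MotFileError(f"line {lineno}: non-positive box size {w}x{h}")
    if frame < 1:
        raise MotFileError(f"line {lineno}: frame index {frame} < 1")
    box = BoundingBox(left, top, w, h)
    if kind == "det":
        return Detection(frame=frame, box=box, confidence=conf)
    return GroundTruthEntry(frame=frame, identity=ident, box=box)


def read_mot_file(path: str | Path, kind: str = "det"):
    """Read a MOT16-dialect text file.

    Parameters
    ----------
    path
        det.txt / gt.txt / result file.
    kind
        ``"det"`` returns :class:`Detection` (the id column is ignored);
        ``"gt"`` or ``"result"`` return :class:`GroundTruthEntry`.

    Entries are returned sorted by frame, preserving file order within a
    frame.  Trailing fields beyond the 7th (visibility/class columns of full
    MOT16 ground truth) are accepted and ignored.
    """
    if kind not in ("det", "gt", "result"):
        raise ValueError(f"kind must be det, gt or result, got {kind!r}")
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such MOT file: {path}")
    entries = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        entries.append(_parse_line(line, lineno, kind))
    entries.sort(key=lambda e: e.frame)  # stable: file order kept within frame
    return entries


def write_result_file(records: Iterable[ResultRecord], path: str | Path) -> None:
    """Write tracker output in the MOT16 result dialect.

    Lines are ``frame,id,x,y,w,h,1,-1,-1,-1`` with the confidence fixed at 1;
    ``read_mot_file(write(x), kind="result")`` reproduces the records.
    """
    path = Path(path)
    lines = []
    for r in sorted(records, key=lambda r: (r.frame, r.identity)):
        b = r.box
        lines.append(
            f"{r.frame},{r.identity},{_fmt(b.left)},{_fmt(b.top)},"
            f"{_fmt(b.width)},{_fmt(b.height)},1,-1,-1,-1"
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _fmt(x: float) -> str:
    """Shortest exact decimal for a coordinate (integers stay integers)."""
    x = float(x)
    return repr(int(x)) if x.is_integer() else repr(x)


def read_embeddings(path: str | Path, dim: int) -> dict[tuple[int, int], np.ndarray]:
    """Read an embedding sidecar: ``frame,ordinal,v1,...,vD`` per line.

    Vectors are renormalized to unit length.  A zero vector or a dimension
    mismatch is rejected with the offending line number.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such embedding file: {path}")
    out: dict[tuple[int, int], np.ndarray] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split(",")
        if len(fields) != 2 + dim:
            raise MotFileError(
                f"line {lineno}: expected 2 keys + {dim} values, got {len(fields)} fields"
            )
        try:
            frame, ordinal = int(fields[0]), int(fields[1])
            vec = np.array([float(f) for f in fields[2:]])
        except ValueError as exc:
            raise MotFileError(f"line {lineno}: non-numeric field ({exc})") from None
        norm = float(np.linalg.norm(vec))
        if norm == 0.0:
            raise MotFileError(f"line {lineno}: zero embedding vector")
        out[(frame, ordinal)] = vec / norm
    return out


def attach_embeddings(
    detections: Iterable[Detection], embeddings: dict[tuple[int, int], np.ndarray]
) -> list[Detection]:
    """Pair detections with sidecar embeddings keyed by (frame, ordinal).

    The ordinal counts detections within each frame in file order.  A
    detection without a sidecar row keeps ``embedding=None``.
    """
    out: list[Detection] = []
    counters: dict[int, int] = {}
    for det in detections:
        ordinal = counters.get(det.frame, 0)
        counters[det.frame] = ordinal + 1
        vec = embeddings.get((det.frame, ordinal))
        out.append(dataclasses.replace(det, embedding=vec))
    return out


def write_embeddings(embeddings: dict[tuple[int, int], np.ndarray], path: str | Path) -> None:
    """Write an embedding sidecar (inverse of :func:`read_embeddings`)."""
    lines = []
    for (frame, ordinal), vec in sorted(embeddings.items()):
        vals = ",".join(f"{v:.8f}" for v in vec)
        lines.append(f"{frame},{ordinal},{vals}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
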