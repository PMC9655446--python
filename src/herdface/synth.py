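"""Seeded synthetic data: embedding clusters, procedural faces, frame streams.

Every downstream stage of the identification pipeline is testable offline
against this module:

* **Embeddings** — each synthetic identity is a unit mean direction in
  d-dimensional space; samples are the mean plus isotropic Gaussian noise of
  scale ``sigma``, renormalized to the unit sphere. Within-identity cosine
  similarity then degrades smoothly as sigma grows, while independent means
  are near-orthogonal for d >> 1 — the geometry a trained face encoder is
  meant to produce.
* **Images** — a procedural "face": a textured disk carrying an
  identity-specific speckle field, two dark eye disks, and a muzzle disk,
  rendered at a known rotation about the face center. Ground-truth bounding
  box and landmarks are returned analytically, so alignment code can be
  checked to sub-degree accuracy.
* **Streams** — fixed-fps frame sequences of one identity with slowly
  varying pose, for the buffered video path.

Everything is driven by integer-seeded generators: the same spec and seed
reproduce byte-identical fixtures on any platform.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import ConfigError
from .geometry import BoundingBox, ImageFrame, Landmarks

__all__ = [
    "SynthIdentity",
    "SynthSpec",
    "make_identities",
    "sample_embedding",
    "sample_embeddings",
    "render_face",
    "make_video",
    "write_bundle",
    "load_truth",
]


@dataclass
class SynthIdentity:
    identity_id: str
    mean: np.ndarray
    appearance_seed: int
    sigma: float = 0.05
    is_mate: bool = True

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        n = np.linalg.norm(self.mean)
        if not math.isclose(n, 1.0, abs_tol=1e-9):
            self.mean = self.mean / n


@dataclass
class SynthSpec:
    """Study-condition knobs for the synthetic world.

    Defaults mirror the desk-scale evaluation regime: 50 enrolled mates and
    10 unenrolled non-mates in a 64-dimensional embedding space with tight
    within-identity noise (sigma = 0.05), 30 fps streams, and 128 px canvases
    whose face geometry keeps all three landmarks inside the face disk.
    """

    n_mates: int = 50
    n_nonmates: int = 10
    dimension: int = 64
    sigma: float = 0.05
    samples_per_identity: int = 25
    seed: int = 0
    canvas: int = 128
    face_radius_frac: float = 0.35
    eye_separation: float = 48.0
    eye_offset_y: float = 16.0
    muzzle_offset: float = 32.0
    rotation_range: float = 30.0
    pattern_cells: int = 12
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.n_mates < 0 or self.n_nonmates < 0:
            raise ConfigError("identity counts must be >= 0")
        if self.dimension < 2:
            raise ConfigError("dimension must be >= 2")
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if self.samples_per_identity < 1:
            raise ConfigError("samples_per_identity must be >= 1")
        if not 0.0 < self.face_radius_frac <= 0.5:
            raise ConfigError("face_radius_frac must be in (0, 0.5]")
        if self.fps <= 0:
            raise ConfigError("fps must be > 0")

    @property
    def face_radius(self) -> float:
        return self.face_radius_frac * self.canvas


def make_identities(spec: SynthSpec) -> list[SynthIdentity]:
    """Draw mate + non-mate identities with unit mean directions.

    Means are independent standard normal vectors, normalized; for d >> 1
    they are nearly orthogonal, emulating a well-trained encoder's identity
    clusters. Mates are named ``C####``, non-mates ``N####``.
    """
    rng = np.random.default_rng(spec.seed)
    identities = []
    for kind, count, prefix in (("mate", spec.n_mates, "C"), ("nonmate", spec.n_nonmates, "N")):
        for i in range(count):
            mean = rng.standard_normal(spec.dimension)
            mean /= np.linalg.norm(mean)
            identities.append(
                SynthIdentity(
                    identity_id=f"{prefix}{i:04d}",
                    mean=mean,
                    appearance_seed=int(rng.integers(0, 2**31 - 1)),
                    sigma=spec.sigma,
                    is_mate=(kind == "mate"),
                )
            )
    return identities


def sample_embedding(identity: SynthIdentity, rng: np.random.Generator) -> np.ndarray:
    """One noisy draw from an identity's cluster, back on the unit sphere.

    ``mean + sigma * N(0, I)`` renormalized; sigma = 0 returns the mean
    exactly. (A Gaussian perturb-and-renormalize, qualitatively a von
    Mises-Fisher-like concentration without the exact density.)
    """
    if identity.sigma == 0:
        return identity.mean.copy()
    vec = identity.mean + identity.sigma * rng.standard_normal(identity.mean.size)
    return vec / np.linalg.norm(vec)


def sample_embeddings(
    identity: SynthIdentity, n: int, rng: np.random.Generator
) -> np.ndarray:
    return np.stack([sample_embedding(identity, rng) for _ in range(n)])


def _landmark_offsets(spec: SynthSpec) -> np.ndarray:
    """Landmark positions relative to the face center (y-down): eyes above,
    muzzle below."""
    s = spec.eye_separation / 2.0
    return np.array(
        [[-s, -spec.eye_offset_y], [s, -spec.eye_offset_y], [0.0, spec.muzzle_offset]]
    )


def _rot(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def render_face(
    identity: SynthIdentity,
    rotation_deg: float,
    spec: SynthSpec,
    center: tuple[float, float] | None = None,
    frame_index: int = 0,
    timestamp_ms: float = 0.0,
    illumination: tuple[int, float] | None = None,
) -> tuple[ImageFrame, BoundingBox, Landmarks]:
    """Render one procedural face at a known rotation with exact ground truth.

    The identity's speckle texture lives in face coordinates, so two renders
    of the same identity at different rotations align to the same chip — the
    property a real face does have and that the toy encoder exploits.

    ``illumination`` is an optional ``(seed, amplitude)`` pair adding a
    smooth seeded lighting field over the canvas; it is what makes two
    frames of one clip differ in appearance, the way lighting and exposure
    drift does on a real farm video.
    """
    if not -180.0 < rotation_deg <= 180.0:
        raise ConfigError("rotation must be in (-180, 180]")
    r = spec.face_radius
    box_half = 1.15 * r
    canvas = spec.canvas
    if 2 * box_half > canvas:
        raise ConfigError("face larger than canvas; increase canvas or shrink face")
    if center is None:
        center = (canvas / 2.0, canvas / 2.0)
    c = np.asarray(center, dtype=float)
    if not (box_half <= c[0] <= canvas - box_half and box_half <= c[1] <= canvas - box_half):
        raise ConfigError("face center too close to the canvas border")

    offs = _landmark_offsets(spec)
    max_lm = float(np.max(np.linalg.norm(offs, axis=1)))
    if max_lm + 8 > box_half:
        raise ConfigError("landmark layout exceeds the face box")

    lm_abs = offs @ _rot(rotation_deg).T + c

    # inverse-rotate every canvas pixel center into face coordinates
    xs = np.arange(canvas) + 0.5
    gx, gy = np.meshgrid(xs, xs)
    rel = np.stack([gx - c[0], gy - c[1]], axis=-1)
    face_xy = rel @ _rot(rotation_deg)  # R(-deg) applied to row vectors

    arng = np.random.default_rng(identity.appearance_seed)
    cells = spec.pattern_cells
    fieldv = arng.uniform(0.0, 1.0, size=(cells, cells))

    # bilinear sample of the identity speckle field over the face disk
    u = np.clip((face_xy[..., 0] / (2 * r) + 0.5) * (cells - 1), 0, cells - 1)
    v = np.clip((face_xy[..., 1] / (2 * r) + 0.5) * (cells - 1), 0, cells - 1)
    u0 = np.floor(u).astype(int)
    v0 = np.floor(v).astype(int)
    u1 = np.minimum(u0 + 1, cells - 1)
    v1 = np.minimum(v0 + 1, cells - 1)
    fu = u - u0
    fv = v - v0
    tex = (
        fieldv[v0, u0] * (1 - fu) * (1 - fv)
        + fieldv[v0, u1] * fu * (1 - fv)
        + fieldv[v1, u0] * (1 - fu) * fv
        + fieldv[v1, u1] * fu * fv
    )

    # mid-gray background so the box/corner region does not dominate the
    # mean-centered toy embedding with an identity-independent pattern
    img = np.full((canvas, canvas), 140.0)
    dist = np.linalg.norm(face_xy, axis=-1)
    face_mask = dist <= r
    img[face_mask] = 40.0 + 200.0 * tex[face_mask]

    for (ox, oy), radius, value in (
        (offs[0], 5.0, 10.0),
        (offs[1], 5.0, 10.0),
        (offs[2], 6.0, 235.0),
    ):
        d = np.linalg.norm(face_xy - np.array([ox, oy]), axis=-1)
        img[d <= radius] = value

    if illumination is not None:
        ill_seed, amplitude = illumination
        ill_rng = np.random.default_rng(int(ill_seed))
        coarse = ill_rng.uniform(-1.0, 1.0, size=(3, 3))
        ui = np.linspace(0, 2, canvas)
        i0 = np.floor(ui).astype(int)
        i1 = np.minimum(i0 + 1, 2)
        fi = ui - i0
        rowsf = coarse[i0][:, i0] * np.outer(1 - fi, 1 - fi)
        rowsf += coarse[i0][:, i1] * np.outer(1 - fi, fi)
        rowsf += coarse[i1][:, i0] * np.outer(fi, 1 - fi)
        rowsf += coarse[i1][:, i1] * np.outer(fi, fi)
        img = img + amplitude * rowsf

    pixels = np.repeat(np.clip(img, 0, 255).astype(np.uint8)[:, :, None], 3, axis=2)
    frame = ImageFrame(pixels, frame_index=frame_index, timestamp_ms=timestamp_ms)
    bbox = BoundingBox(
        c[0] - box_half, c[1] - box_half, c[0] + box_half, c[1] + box_half, confidence=1.0
    )
    lms = Landmarks(tuple(lm_abs[0]), tuple(lm_abs[1]), tuple(lm_abs[2]))
    return frame, bbox, lms


@dataclass
class MotionSpec:
    """Slow pose drift for a synthetic clip: sinusoidal head turn + sway,
    plus per-frame lighting drift so consecutive chips are not identical."""

    rotation_amplitude_deg: float = 20.0
    rotation_period_s: float = 4.0
    sway_amplitude_px: float = 0.0
    sway_period_s: float = 6.0
    illumination_amplitude: float = 40.0


def make_video(
    identity: SynthIdentity,
    n_frames: int,
    fps: float,
    spec: SynthSpec,
    motion: MotionSpec | None = None,
) -> list[tuple[ImageFrame, BoundingBox, Landmarks]]:
    """Fixed-fps single-identity clip with slowly varying rotation/position."""
    if n_frames < 1:
        raise ConfigError("n_frames must be >= 1")
    motion = motion or MotionSpec()
    out = []
    c0 = spec.canvas / 2.0
    for t in range(n_frames):
        sec = t / fps
        theta = motion.rotation_amplitude_deg * math.sin(
            2 * math.pi * sec / motion.rotation_period_s
        )
        sway = motion.sway_amplitude_px * math.sin(2 * math.pi * sec / motion.sway_period_s)
        illumination = None
        if motion.illumination_amplitude > 0:
            illumination = (identity.appearance_seed + 7919 * t, motion.illumination_amplitude)
        out.append(
            render_face(
                identity,
                theta,
                spec,
                center=(c0 + sway, c0),
                frame_index=t,
                timestamp_ms=1000.0 * t / fps,
                illumination=illumination,
            )
        )
    return out


TRUTH_COLUMNS = [
    "path",
    "frame",
    "identity",
    "is_mate",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "conf",
    "lx",
    "ly",
    "rx",
    "ry",
    "mx",
    "my",
]


def write_bundle(
    spec: SynthSpec,
    out_dir,
    frames_per_identity: int = 8,
    motion: MotionSpec | None = None,
) -> Path:
    """Write a fixture bundle: frames/<id>/*.png + truth.csv + spec.json."""
    import pandas as pd

    out_dir = Path(out_dir)
    (out_dir / "frames").mkdir(parents=True, exist_ok=True)
    identities = make_identities(spec)
    rows = []
    for ident in identities:
        clip = make_video(ident, frames_per_identity, spec.fps, spec, motion)
        id_dir = out_dir / "frames" / ident.identity_id
        id_dir.mkdir(exist_ok=True)
        for frame, box, lm in clip:
            rel = f"frames/{ident.identity_id}/f{frame.frame_index:06d}.png"
            Image.fromarray(frame.pixels).save(out_dir / rel)
            rows.append(
                [
                    rel,
                    frame.frame_index,
                    ident.identity_id,
                    int(ident.is_mate),
                    box.x_min,
                    box.y_min,
                    box.x_max,
                    box.y_max,
                    box.confidence,
                    *lm.left_eye,
                    *lm.right_eye,
                    *lm.muzzle,
                ]
            )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(out_dir / "truth.csv", index=False)
    (out_dir / "spec.json").write_text(json.dumps(asdict(spec), indent=2) + "\n")
    return out_dir


def load_truth(bundle_dir) -> "pd.DataFrame":
    import pandas as pd

    return pd.read_csv(Path(bundle_dir) / "truth.csv")
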