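"""End-to-end composition of the four pipeline stages on frames and bundles.

detect (confidence filter) -> crop (squarify + landmark alignment) ->
encode (pluggable backend) -> lookup (rank/threshold/vote). Detections and
landmarks come from a pluggable source; the bundled source reads the
ground-truth table that ships with synthetic fixture bundles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .config import PipelineConfig
from .encoding import EncoderBackend, get_backend
from .exceptions import InvalidInputError
from .gallery import EnrollmentConfig, Gallery, enroll
from .geometry import (
    BoundingBox,
    ChipFace,
    ImageFrame,
    Landmarks,
    align_chip,
    filter_detections,
    squarify,
)
from .lookup import MatchResult, UNIDENTIFIED, apply_threshold, rank, vote_top_r
from .stream import Buffer, apply_buf_threshold, buffer_vote, sample_indices

__all__ = ["Detection", "FacePipeline", "load_frame", "read_detections"]


@dataclass
class Detection:
    """One frame's detector/landmark output handed to the pipeline."""

    box: BoundingBox
    landmarks: Landmarks


def load_frame(path, frame_index: int = 0, timestamp_ms: float = 0.0) -> ImageFrame:
    with Image.open(path) as img:
        pixels = np.asarray(img.convert("RGB"))
    return ImageFrame(pixels, frame_index=frame_index, timestamp_ms=timestamp_ms)


def read_detections(csv_path) -> pd.DataFrame:
    """Read a detections/landmarks table (the fixture truth.csv layout)."""
    df = pd.read_csv(csv_path)
    needed = {"x_min", "y_min", "x_max", "y_max", "conf", "lx", "ly", "rx", "ry", "mx", "my"}
    missing = needed - set(df.columns)
    if missing:
        raise InvalidInputError(f"detections table missing columns: {sorted(missing)}")
    return df


def detection_from_row(row) -> Detection:
    return Detection(
        box=BoundingBox(
            row["x_min"], row["y_min"], row["x_max"], row["y_max"], row["conf"]
        ),
        landmarks=Landmarks(
            (row["lx"], row["ly"]), (row["rx"], row["ry"]), (row["mx"], row["my"])
        ),
    )


class FacePipeline:
    """Still-image and streaming identification runner."""

    def __init__(self, config: PipelineConfig | None = None, encoder: EncoderBackend | None = None):
        self.config = config or PipelineConfig()
        self.encoder = encoder or get_backend(
            self.config.encoder_backend, dimension=self.config.dimension
        )

    # -- chip extraction ---------------------------------------------------

    def extract_chip(self, frame: ImageFrame, det: Detection) -> ChipFace | None:
        """Confidence-filter, squarify, and align one detection into a chip."""
        best = filter_detections([det.box], self.config.detector_min_conf)
        if best is None:
            return None
        sq = squarify(best, frame.width, frame.height)
        return align_chip(frame, sq, det.landmarks, self.config.chip_side)

    def encode_chip(self, chip: ChipFace) -> np.ndarray:
        return self.encoder.encode(chip)

    # -- still image -------------------------------------------------------

    def identify_frame(
        self, frame: ImageFrame, det: Detection, gallery: Gallery
    ) -> MatchResult | None:
        """Full single-image pipeline; None when no confident face is found."""
        chip = self.extract_chip(frame, det)
        if chip is None:
            return None
        cfg = self.config.lookup
        cands = rank(gallery, self.encode_chip(chip), cfg.candidate_list_length)
        result = apply_threshold(cands, cfg.threshold)
        if result.accepted and cfg.top_r > 1:
            result.pip_id = vote_top_r(cands, cfg.top_r)
        result.frame_index = frame.frame_index
        return result

    # -- enrollment --------------------------------------------------------

    def enroll_bundle(
        self,
        bundle_dir,
        enrollment: EnrollmentConfig | None = None,
        gallery: Gallery | None = None,
    ) -> Gallery:
        """Detect/crop/encode every bundle frame and diversity-enroll per identity."""
        bundle_dir = Path(bundle_dir)
        truth = read_detections(bundle_dir / "truth.csv")
        if "identity" not in truth.columns or "path" not in truth.columns:
            raise InvalidInputError("bundle truth.csv needs identity and path columns")
        gallery = gallery if gallery is not None else Gallery(encoder_name=self.config.encoder_backend)
        enrollment = enrollment or EnrollmentConfig()
        if "is_mate" in truth.columns:  # bundles mark unenrollable non-mates
            truth = truth[truth["is_mate"].astype(int) == 1]
        for identity, group in truth.groupby("identity", sort=True):
            embeddings, refs = [], []
            for _, row in group.sort_values("frame").iterrows():
                frame = load_frame(bundle_dir / row["path"], int(row["frame"]))
                chip = self.extract_chip(frame, detection_from_row(row))
                if chip is None:
                    continue
                embeddings.append(self.encode_chip(chip))
                refs.append(str(row["path"]))
            if not embeddings:
                continue
            enroll(gallery, str(identity), embeddings, enrollment, chip_refs=refs)
        return gallery

    # -- streaming ---------------------------------------------------------

    def watch(
        self,
        frames: list[tuple[ImageFrame, Detection]],
        gallery: Gallery,
    ) -> pd.DataFrame:
        """Sample every n-th frame, maintain the FIFO buffer, emit one row per sample."""
        scfg = self.config.stream
        indices = set(sample_indices(len(frames), scfg.sample_interval))
        buf = Buffer(scfg.buffer_size)
        rows = []
        for pos, (frame, det) in enumerate(frames):
            if pos not in indices:
                continue
            result = self.identify_frame(frame, det, gallery)
            pip_id = result.pip_id if result is not None else UNIDENTIFIED
            pip_score = result.pip_score if result is not None else float("nan")
            buf.push(pip_id)
            vote = buffer_vote(buf)
            if vote.ready:
                vote = apply_buf_threshold(vote, scfg.buf_threshold)
            rows.append(
                {
                    "sampled_frame_index": frame.frame_index,
                    "pipID": pip_id,
                    "pipScore": pip_score,
                    "ready": vote.ready,
                    "bufID": vote.buf_id if vote.ready else "",
                    "bufScore": vote.buf_score,
                }
            )
        return pd.DataFrame(rows)
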