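"""Enrollment gallery: per-identity chip/embedding records with persistence.

The gallery is the reference database of an open-set identification system:
for each enrolled individual ("mate") it holds up to ``nim_target`` embedding
records. Enrollment applies greedy diversity sampling — a candidate is kept
only when its cosine similarity to every previously kept sample of the same
identity stays strictly below ``diversity_threshold`` — so near-duplicate
consecutive video frames do not flood the database.

On disk a gallery is a directory::

    manifest.json     format version, embedding dimension, encoder name, ids
    embeddings.csv    record_id, identity_id, order_index, chip_ref, e0..e{d-1}
    chips/            optional PNG chip crops

Embeddings are written as decimal text with 17 significant digits, so a
save/load round trip is bit-exact for float64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import as_embedding, cosine_similarity
from .exceptions import (
    DuplicateIdentityError,
    GalleryNotFoundError,
    GalleryVersionError,
    IdentityNotFoundError,
    InvalidInputError,
    MalformedGalleryError,
)

__all__ = [
    "GalleryRecord",
    "Gallery",
    "EnrollmentConfig",
    "diversity_filter",
    "enroll",
    "remove_identity",
    "save_gallery",
    "load_gallery",
]

FORMAT_VERSION = 1


@dataclass(frozen=True)
class GalleryRecord:
    identity_id: str
    embedding: np.ndarray
    chip_ref: str | None = None
    order_index: int = 0

    def __post_init__(self) -> None:
        if not self.identity_id:
            raise InvalidInputError("identity_id must be non-empty")
        if self.order_index < 0:
            raise InvalidInputError("order_index must be >= 0")
        object.__setattr__(self, "embedding", as_embedding(self.embedding))

    def __eq__(self, other) -> bool:
        if not isinstance(other, GalleryRecord):
            return NotImplemented
        return (
            self.identity_id == other.identity_id
            and self.order_index == other.order_index
            and self.chip_ref == other.chip_ref
            and np.array_equal(self.embedding, other.embedding)
        )


@dataclass
class EnrollmentConfig:
    """Enrollment policy: records per identity and the diversity rule."""

    nim_target: int = 25
    diversity_threshold: float = 0.9
    diversity_feature_backend: str = "toy"

    def __post_init__(self) -> None:
        if self.nim_target < 1:
            raise InvalidInputError("nim_target must be >= 1")
        if not -1.0 <= self.diversity_threshold <= 1.0:
            raise InvalidInputError("diversity_threshold outside [-1, 1]")


@dataclass
class Gallery:
    """Collection of enrolled records; N and per-identity counts are derived."""

    records: list[GalleryRecord] = field(default_factory=list)
    dimension: int | None = None
    encoder_name: str = "toy"

    def __post_init__(self) -> None:
        for r in self.records:
            self._check_dimension(r)

    def _check_dimension(self, record: GalleryRecord) -> None:
        if self.dimension is None:
            self.dimension = int(record.embedding.size)
        elif record.embedding.size != self.dimension:
            raise InvalidInputError(
                f"record dimension {record.embedding.size} != gallery {self.dimension}"
            )

    @property
    def n_identities(self) -> int:
        """N: number of distinct enrolled identities."""
        return len({r.identity_id for r in self.records})

    @property
    def identities(self) -> list[str]:
        return sorted({r.identity_id for r in self.records})

    def nim(self, identity_id: str) -> int:
        """Number of enrolled images for one identity."""
        return sum(r.identity_id == identity_id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, identity_id: str) -> bool:
        return any(r.identity_id == identity_id for r in self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Gallery):
            return NotImplemented
        return self.records == other.records and self.encoder_name == other.encoder_name

    def records_for(self, identity_id: str) -> list[GalleryRecord]:
        return [r for r in self.records if r.identity_id == identity_id]

    def embedding_matrix(self) -> np.ndarray:
        if not self.records:
            return np.empty((0, self.dimension or 0))
        return np.stack([r.embedding for r in self.records])


def diversity_filter(
    candidates, threshold: float, max_count: int
) -> list[int]:
    """Greedy diversity selection over an ordered embedding stream.

    The first candidate is always kept; each later one is kept iff its
    maximum cosine similarity to everything kept so far is strictly below
    ``threshold``. Selection stops at ``max_count`` kept samples. Returns the
    indices of kept candidates, in order.
    """
    if not -1.0 <= threshold <= 1.0:
        raise InvalidInputError("threshold outside [-1, 1]")
    if max_count < 1:
        raise InvalidInputError("max_count must be >= 1")
    kept: list[int] = []
    kept_vecs: list[np.ndarray] = []
    for i, cand in enumerate(candidates):
        vec = as_embedding(cand)
        if not kept:
            accept = True
        else:
            accept = max(cosine_similarity(vec, k) for k in kept_vecs) < threshold
        if accept:
            kept.append(i)
            kept_vecs.append(vec)
            if len(kept) >= max_count:
                break
    return kept


def enroll(
    gallery: Gallery,
    identity_id: str,
    embeddings,
    config: EnrollmentConfig | None = None,
    chip_refs: list[str] | None = None,
    merge: bool = False,
) -> Gallery:
    """Diversity-filter a candidate stream and append records for one identity.

    Re-enrolling an existing identity raises unless ``merge`` is set, in
    which case new records continue that identity's order indices and the
    diversity rule is applied against the already-stored embeddings too.
    Mutates and returns ``gallery``.
    """
    config = config or EnrollmentConfig()
    if not identity_id:
        raise InvalidInputError("identity_id must be non-empty")
    embeddings = [as_embedding(e) for e in embeddings]
    if not embeddings:
        raise InvalidInputError("no candidate embeddings supplied")
    if chip_refs is not None and len(chip_refs) != len(embeddings):
        raise InvalidInputError("chip_refs length must match embeddings")

    existing = gallery.records_for(identity_id)
    if existing and not merge:
        raise DuplicateIdentityError(f"identity {identity_id!r} already enrolled")

    already = [r.embedding for r in existing]
    budget = config.nim_target - len(already)
    if budget <= 0:
        return gallery
    # replay the greedy rule with prior records pre-seeded
    kept: list[int] = []
    for i, vec in enumerate(embeddings):
        pool = already + [embeddings[j] for j in kept]
        if not pool or max(cosine_similarity(vec, k) for k in pool) < config.diversity_threshold:
            kept.append(i)
            if len(kept) >= budget:
                break

    start = max((r.order_index for r in existing), default=-1) + 1
    for offset, i in enumerate(kept):
        rec = GalleryRecord(
            identity_id=identity_id,
            embedding=embeddings[i],
            chip_ref=chip_refs[i] if chip_refs is not None else None,
            order_index=start + offset,
        )
        gallery._check_dimension(rec)
        gallery.records.append(rec)
    return gallery


def remove_identity(gallery: Gallery, identity_id: str) -> Gallery:
    """Delete every record of one identity; no model retraining is implied."""
    if identity_id not in gallery:
        raise IdentityNotFoundError(identity_id)
    gallery.records = [r for r in gallery.records if r.identity_id != identity_id]
    return gallery


def save_gallery(gallery: Gallery, path) -> None:
    """Write a gallery directory (manifest.json + embeddings.csv)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    d = gallery.dimension or 0
    manifest = {
        "format_version": FORMAT_VERSION,
        "dimension": d,
        "encoder": gallery.encoder_name,
        "identities": gallery.identities,
        "n_records": len(gallery),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    cols = ["record_id", "identity_id", "order_index", "chip_ref"] + [
        f"e{i}" for i in range(d)
    ]
    rows = []
    for rid, r in enumerate(gallery.records):
        rows.append(
            [rid, r.identity_id, r.order_index, r.chip_ref or ""]
            + [f"{v:.17g}" for v in r.embedding]
        )
    pd.DataFrame(rows, columns=cols).to_csv(path / "embeddings.csv", index=False)


def load_gallery(path) -> Gallery:
    """Read a gallery directory written by :func:`save_gallery`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise GalleryNotFoundError(f"no manifest.json under {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise MalformedGalleryError(f"unparseable manifest: {exc}") from exc
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise GalleryVersionError(
            f"gallery format version {version!r}, expected {FORMAT_VERSION}"
        )
    d = int(manifest.get("dimension", 0))
    csv_path = path / "embeddings.csv"
    if not csv_path.exists():
        raise GalleryNotFoundError(f"missing embeddings.csv under {path}")
    try:
        # dtype=str so float64 components re-parse exactly via Python's float()
        df = pd.read_csv(csv_path, keep_default_na=False, dtype=str)
    except Exception as exc:
        raise MalformedGalleryError(f"unparseable embeddings.csv: {exc}") from exc

    ecols = [c for c in df.columns if c.startswith("e") and c[1:].isdigit()]
    ecols.sort(key=lambda c: int(c[1:]))
    if len(ecols) != d:
        raise MalformedGalleryError(
            f"embeddings.csv has {len(ecols)} components, manifest says {d}"
        )
    records = []
    try:
        for _, row in df.iterrows():
            vec = np.array([float(row[c]) for c in ecols])
            records.append(
                GalleryRecord(
                    identity_id=str(row["identity_id"]),
                    embedding=vec,
                    chip_ref=str(row["chip_ref"]) or None,
                    order_index=int(row["order_index"]),
                )
            )
    except (KeyError, ValueError) as exc:
        raise MalformedGalleryError(f"bad embeddings.csv row: {exc}") from exc
    if int(manifest.get("n_records", len(records))) != len(records):
        raise MalformedGalleryError("record count disagrees with manifest")
    return Gallery(
        records=records,
        dimension=d if records else (d or None),
        encoder_name=str(manifest.get("encoder", "toy")),
    )
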