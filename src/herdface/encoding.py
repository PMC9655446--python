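"""Face embeddings, cosine similarity, and the encoder-backend contract.

An encoder maps an aligned chip face to a fixed-dimension real vector whose
direction characterizes the individual: embeddings of the same animal point
nearly the same way on the unit hypersphere, embeddings of different animals
do not. Production systems plug a trained CNN backbone in behind
:class:`EncoderBackend`; the package ships a deterministic block-average
:class:`ToyEncoder` so that every downstream stage runs offline.

Similarity is the cosine of the angle between two embeddings,

    sim(A, B) = sum_i A_i B_i / (||A|| ||B||)   in [-1, 1],

with 1 a perfect match and -1 the exact opposite.
"""

from __future__ import annotations

import math
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from .exceptions import InvalidInputError
from .geometry import ChipFace

__all__ = [
    "DEFAULT_DIMENSION",
    "as_embedding",
    "cosine_similarity",
    "EncoderBackend",
    "ToyEncoder",
    "register_backend",
    "get_backend",
    "available_backends",
]

#: Embedding width of the reference CNN backbone; the toy encoder defaults
#: to 64 for desk-scale work.
DEFAULT_DIMENSION = 512


def as_embedding(vec, *, allow_zero: bool = False) -> np.ndarray:
    """Validate and return a 1-D float64 embedding vector."""
    arr = np.asarray(vec, dtype=np.float64)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidInputError("embedding must be a non-empty 1-D vector")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("embedding has non-finite components")
    if not allow_zero and not np.any(arr):
        raise InvalidInputError("zero vector has no direction")
    return arr


def cosine_similarity(a, b) -> float:
    """Cosine similarity between two equal-dimension non-zero vectors."""
    va = as_embedding(a)
    vb = as_embedding(b)
    if va.shape != vb.shape:
        raise InvalidInputError(f"dimension mismatch: {va.size} vs {vb.size}")
    return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))


@runtime_checkable
class EncoderBackend(Protocol):
    """Contract for pluggable encoders: a pure, deterministic chip -> vector map."""

    dimension: int

    def encode(self, chip: ChipFace) -> np.ndarray:  # pragma: no cover - protocol
        ...


class ToyEncoder:
    """Deterministic stand-in encoder: mean-centered coarse intensity grid.

    The chip is converted to grayscale, block-averaged onto a coarse grid,
    flattened to ``dimension`` values and mean-centered. Being a linear map
    of pixel intensities, it is exactly sign-flipped by a photometric
    negative and identical for identical pixels — enough structure to
    exercise enrollment, lookup and evaluation end to end.
    """

    def __init__(self, dimension: int = 64):
        if dimension < 2:
            raise InvalidInputError("dimension must be >= 2")
        self.dimension = int(dimension)
        self._grid = math.ceil(math.sqrt(self.dimension))

    def encode(self, chip: ChipFace) -> np.ndarray:
        pix = chip.pixels.astype(np.float64)
        if pix.ndim == 3:
            gray = pix[:, :, 0] * 0.299 + pix[:, :, 1] * 0.587 + pix[:, :, 2] * 0.114
        else:
            gray = pix
        g = self._grid
        rows = np.array_split(gray, g, axis=0)
        cells = [np.array_split(r, g, axis=1) for r in rows]
        means = np.array([[c.mean() for c in row] for row in cells], dtype=np.float64)
        flat = means.ravel()[: self.dimension]
        return flat - flat.mean()

    def encode_batch(self, chips: list[ChipFace]) -> np.ndarray:
        return np.stack([self.encode(c) for c in chips])

    def __repr__(self) -> str:
        return f"ToyEncoder(dimension={self.dimension})"


_BACKENDS: dict[str, Callable[..., EncoderBackend]] = {}


def register_backend(name: str, factory: Callable[..., EncoderBackend]) -> None:
    """Register an encoder factory under a configuration name."""
    _BACKENDS[name] = factory


def get_backend(name: str, **kwargs) -> EncoderBackend:
    """Instantiate a registered encoder backend by name."""
    try:
        factory = _BACKENDS[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown encoder backend {name!r}; known: {sorted(_BACKENDS)}"
        ) from None
    return factory(**kwargs)


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


register_backend("toy", ToyEncoder)
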