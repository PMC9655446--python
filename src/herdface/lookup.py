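"""Chip-level face lookup: similarity ranking, thresholding, top-R voting.

A query embedding is compared against *every* record in the gallery (chip
level, so several candidates may share an identity) and the top ``L``
candidates are returned by descending cosine similarity. The top candidate's
identity is accepted as ``pipID`` only when its score is strictly greater
than the pipeline threshold ``T``; otherwise the result is the distinguished
value :data:`UNIDENTIFIED` — either a face not in the database or a match
too weak to trust. Top-R voting picks the identity occurring most often
among the first R candidates.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .encoding import as_embedding
from .exceptions import EmptyGalleryError, InvalidInputError
from .gallery import Gallery, GalleryRecord

__all__ = [
    "UNIDENTIFIED",
    "Candidate",
    "MatchResult",
    "LookupConfig",
    "rank",
    "apply_threshold",
    "vote_top_r",
    "identify",
]

#: Distinguished identity value for a rejected / empty lookup.
UNIDENTIFIED = "UNIDENTIFIED"


@dataclass(frozen=True)
class Candidate:
    record: GalleryRecord
    score: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.score <= 1.0 + 1e-9:
            raise InvalidInputError(f"score {self.score} outside [-1, 1]")

    @property
    def identity_id(self) -> str:
        return self.record.identity_id


@dataclass
class MatchResult:
    """Ranked candidates plus the thresholded pipeline decision."""

    candidates: list[Candidate]
    pip_id: str
    pip_score: float
    frame_index: int | None = None

    @property
    def accepted(self) -> bool:
        return self.pip_id != UNIDENTIFIED


@dataclass
class LookupConfig:
    """Lookup parameters: threshold T, list length L, examined rank R <= L."""

    threshold: float = 0.0
    candidate_list_length: int = 10
    top_r: int = 1

    def __post_init__(self) -> None:
        if not -1.0 <= self.threshold <= 1.0:
            raise InvalidInputError("threshold outside [-1, 1]")
        if self.candidate_list_length < 1 or self.top_r < 1:
            raise InvalidInputError("L and R must be >= 1")
        if self.top_r > self.candidate_list_length:
            raise InvalidInputError("R must be <= L")


def rank(gallery: Gallery, query, L: int = 10) -> list[Candidate]:
    """Top-L gallery records by cosine similarity to the query, descending.

    Ties are broken by (identity_id, order_index) ascending so that results
    are deterministic.
    """
    if len(gallery) == 0:
        raise EmptyGalleryError("cannot rank against an empty gallery")
    if L < 1:
        raise InvalidInputError("L must be >= 1")
    q = as_embedding(query)
    mat = gallery.embedding_matrix()
    if q.size != mat.shape[1]:
        raise InvalidInputError(
            f"query dimension {q.size} != gallery dimension {mat.shape[1]}"
        )
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        raise InvalidInputError("gallery contains a zero embedding")
    sims = mat @ q / (norms * np.linalg.norm(q))
    order = sorted(
        range(len(gallery)),
        key=lambda i: (-sims[i], gallery.records[i].identity_id, gallery.records[i].order_index),
    )
    return [Candidate(gallery.records[i], float(sims[i])) for i in order[:L]]


def apply_threshold(candidates: list[Candidate], threshold: float) -> MatchResult:
    """Accept the top candidate's identity iff its score is strictly > T."""
    if not candidates:
        return MatchResult(candidates=[], pip_id=UNIDENTIFIED, pip_score=math.nan)
    top = candidates[0]
    pip_id = top.identity_id if top.score > threshold else UNIDENTIFIED
    return MatchResult(candidates=list(candidates), pip_id=pip_id, pip_score=top.score)


def vote_top_r(candidates: list[Candidate], R: int) -> str:
    """Most frequent identity among the first ``min(R, len)`` candidates.

    Ties go to the identity holding the higher best score among the tied
    ones, then lexicographically smaller id.
    """
    if R < 1:
        raise InvalidInputError("R must be >= 1")
    if not candidates:
        raise InvalidInputError("cannot vote over an empty candidate list")
    window = candidates[: min(R, len(candidates))]
    counts = Counter(c.identity_id for c in window)
    best_score = {}
    for c in window:
        best_score[c.identity_id] = max(best_score.get(c.identity_id, -2.0), c.score)
    return min(counts, key=lambda ident: (-counts[ident], -best_score[ident], ident))


def identify(
    gallery: Gallery, query, config: LookupConfig | None = None, frame_index: int | None = None
) -> MatchResult:
    """Full lookup: rank, threshold, and (when R > 1) re-vote the accepted id."""
    config = config or LookupConfig()
    candidates = rank(gallery, query, config.candidate_list_length)
    result = apply_threshold(candidates, config.threshold)
    if result.accepted and config.top_r > 1:
        result.pip_id = vote_top_r(candidates, config.top_r)
    result.frame_index = frame_index
    return result
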