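"""Open-set identification evaluation: FPIR, FNIR, TPIR, CMC, DET, EER.

Vocabulary follows the NIST face-recognition-vendor-test identification
track. A *mate* probe has its identity enrolled in the gallery; a *non-mate*
probe does not. Two error conditions are counted:

* **miss** — a mate search whose true identity falls outside the top R
  ranks or whose score fails the acceptance rule (strict ``> T``);
* **false positive** — a non-mate search whose top candidate is accepted.

These accumulate into rates over the searches attempted::

    FPIR(N, T)    = #false positives / #non-mate searches
    FNIR(N, R, T) = #misses          / #mate searches
    TPIR(N, R, T) = 1 - FNIR(N, R, T)
    CMC(N, R)     = 1 - FNIR(N, R, 0)        (threshold fully relaxed)

The DET curve traces (FPIR, FNIR) over a threshold grid; the equal error
rate (EER) is the crossing point FNIR = FPIR, located by linear
interpolation between grid points. Rates with an empty denominator are
reported as NaN, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .lookup import Candidate, MatchResult, UNIDENTIFIED, rank, vote_top_r

__all__ = [
    "NONMATE",
    "SearchOutcome",
    "MetricCurves",
    "Rates",
    "outcome_from_match",
    "is_miss",
    "is_false_positive",
    "identification_rates",
    "det_and_eer",
    "unique_id_counts",
    "landmark_error_rate",
    "SweepSpec",
    "run_sweep",
]

#: Probe-identity marker for non-mate (unenrolled) searches.
NONMATE = "NONMATE"


@dataclass
class SearchOutcome:
    """One probe search against the gallery, reduced to what scoring needs."""

    probe_id: str
    is_mate: bool
    candidates: list[tuple[str, float]]
    rank_of_true: int | None = None
    top_score: float = math.nan

    def __post_init__(self) -> None:
        if self.is_mate and (not self.probe_id or self.probe_id == NONMATE):
            raise InvalidInputError("mate outcome needs a real probe identity")
        if not self.is_mate and self.rank_of_true is not None:
            raise InvalidInputError("non-mate outcome cannot have a true rank")

    def true_score(self) -> float:
        """Best score among candidates carrying the true identity."""
        scores = [s for ident, s in self.candidates if ident == self.probe_id]
        return max(scores) if scores else math.nan


def outcome_from_match(
    probe_id: str, is_mate: bool, candidates: list[Candidate] | MatchResult
) -> SearchOutcome:
    """Build a SearchOutcome from a ranked candidate list."""
    if isinstance(candidates, MatchResult):
        candidates = candidates.candidates
    pairs = [(c.identity_id, c.score) for c in candidates]
    rank_of_true = None
    if is_mate:
        for i, (ident, _) in enumerate(pairs, start=1):
            if ident == probe_id:
                rank_of_true = i
                break
    return SearchOutcome(
        probe_id=probe_id if is_mate else NONMATE,
        is_mate=is_mate,
        candidates=pairs,
        rank_of_true=rank_of_true,
        top_score=pairs[0][1] if pairs else math.nan,
    )


def is_miss(outcome: SearchOutcome, R: int, T: float) -> bool:
    """A mate search misses when the true id is out of the top R or its
    score fails the strict-``>`` acceptance rule."""
    if not outcome.is_mate:
        raise InvalidInputError("is_miss applies to mate searches only")
    if R < 1:
        raise InvalidInputError("R must be >= 1")
    if outcome.rank_of_true is None or outcome.rank_of_true > R:
        return True
    return not outcome.true_score() > T


def is_false_positive(outcome: SearchOutcome, T: float) -> bool:
    """A non-mate search false-alarms when its top candidate is accepted."""
    if outcome.is_mate:
        raise InvalidInputError("is_false_positive applies to non-mate searches only")
    return bool(outcome.top_score > T)


@dataclass
class Rates:
    fpir: float
    fnir: float
    tpir: float
    cmc: float


def identification_rates(
    outcomes: list[SearchOutcome], R: int, T: float
) -> Rates:
    """FPIR/FNIR/TPIR at (R, T) and CMC at the same R with T = 0.

    Either rate is NaN when its denominator (mate or non-mate searches
    attempted) is empty.
    """
    if not outcomes:
        raise InvalidInputError("no outcomes supplied")
    mates = [o for o in outcomes if o.is_mate]
    nonmates = [o for o in outcomes if not o.is_mate]
    fnir = (
        sum(is_miss(o, R, T) for o in mates) / len(mates) if mates else math.nan
    )
    fpir = (
        sum(is_false_positive(o, T) for o in nonmates) / len(nonmates)
        if nonmates
        else math.nan
    )
    cmc = (
        sum(not is_miss(o, R, 0.0) for o in mates) / len(mates) if mates else math.nan
    )
    return Rates(fpir=fpir, fnir=fnir, tpir=1.0 - fnir, cmc=cmc)


@dataclass
class MetricCurves:
    """FPIR/FNIR over a threshold grid plus the interpolated EER point."""

    thresholds: np.ndarray
    fpir: np.ndarray
    fnir: np.ndarray
    eer_threshold: float
    eer_rate: float
    crossed: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpir": self.fpir, "fnir": self.fnir}
        )


def det_and_eer(
    outcomes: list[SearchOutcome], threshold_grid, R: int = 1
) -> MetricCurves:
    """Evaluate the DET trade-off on a grid and locate the EER crossing.

    The EER is found by linear interpolation on the first grid segment where
    FNIR - FPIR changes sign. If the curves never cross on the grid, the
    closest-gap grid point is reported with ``crossed = False``.
    """
    grid = np.asarray(threshold_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise InvalidInputError("threshold grid must be ascending with >= 2 points")
    if not any(o.is_mate for o in outcomes) or not any(not o.is_mate for o in outcomes):
        raise InvalidInputError("DET needs both mate and non-mate searches")

    fnir = np.empty_like(grid)
    fpir = np.empty_like(grid)
    for i, t in enumerate(grid):
        r = identification_rates(outcomes, R, float(t))
        fnir[i] = r.fnir
        fpir[i] = r.fpir

    diff = fnir - fpir
    eer_t = eer_rate = None
    crossed = False
    for i in range(grid.size - 1):
        d0, d1 = diff[i], diff[i + 1]
        if d0 == 0.0:
            eer_t, eer_rate, crossed = float(grid[i]), float(fnir[i]), True
            break
        if d0 * d1 < 0:
            frac = d0 / (d0 - d1)
            eer_t = float(grid[i] + frac * (grid[i + 1] - grid[i]))
            f0 = fnir[i] + frac * (fnir[i + 1] - fnir[i])
            p0 = fpir[i] + frac * (fpir[i + 1] - fpir[i])
            eer_rate = float(0.5 * (f0 + p0))
            crossed = True
            break
    if not crossed:
        if diff[-1] == 0.0:
            eer_t, eer_rate, crossed = float(grid[-1]), float(fnir[-1]), True
        else:
            j = int(np.argmin(np.abs(diff)))
            eer_t = float(grid[j])
            eer_rate = float(0.5 * (fnir[j] + fpir[j]))
    return MetricCurves(
        thresholds=grid,
        fpir=fpir,
        fnir=fnir,
        eer_threshold=eer_t,
        eer_rate=eer_rate,
        crossed=crossed,
    )


def unique_id_counts(
    outcomes: list[SearchOutcome], R: int, T: float
) -> tuple[int, int]:
    """Distinct mate ids hit at least once, and distinct gallery ids wrongly
    accepted across non-mate searches."""
    hit_ids = {
        o.probe_id for o in outcomes if o.is_mate and not is_miss(o, R, T)
    }
    fp_ids = set()
    for o in outcomes:
        if not o.is_mate and is_false_positive(o, T) and o.candidates:
            fp_ids.add(o.candidates[0][0])
    return len(hit_ids), len(fp_ids)


def landmark_error_rate(mse: float, width: float) -> float:
    """Landmark regression error as a percent of the chip width.

    An MSE of s square pixels corresponds to an error swing within a circle
    of radius sqrt(s); the rate is 100 * sqrt(mse) / width, to 2 decimals
    (MSE 9.2 on a 224 px chip -> 1.35%).
    """
    if mse < 0:
        raise InvalidInputError("mse must be >= 0")
    if width <= 0:
        raise InvalidInputError("width must be > 0")
    return round(100.0 * math.sqrt(mse) / width, 2)


# ---------------------------------------------------------------------------
# outcome (de)serialization for the CSV interface
# ---------------------------------------------------------------------------


def outcomes_to_frame(outcomes: list[SearchOutcome]) -> pd.DataFrame:
    """Flatten outcomes to a table; candidate lists encode as id:score|..."""
    rows = []
    for o in outcomes:
        rows.append(
            {
                "probe_id": o.probe_id,
                "is_mate": int(o.is_mate),
                "rank_of_true": "" if o.rank_of_true is None else o.rank_of_true,
                "top_score": o.top_score,
                "candidates": "|".join(f"{i}:{s:.12g}" for i, s in o.candidates),
            }
        )
    return pd.DataFrame(rows)


def outcomes_from_frame(df: pd.DataFrame) -> list[SearchOutcome]:
    out = []
    for _, row in df.iterrows():
        cand_field = row.get("candidates", "")
        pairs = []
        if isinstance(cand_field, str) and cand_field:
            for item in cand_field.split("|"):
                ident, _, score = item.rpartition(":")
                pairs.append((ident, float(score)))
        rot = row.get("rank_of_true", "")
        rank_of_true = None if rot in ("", None) or pd.isna(rot) else int(rot)
        out.append(
            SearchOutcome(
                probe_id=str(row["probe_id"]),
                is_mate=bool(int(row["is_mate"])),
                candidates=pairs,
                rank_of_true=rank_of_true,
                top_score=float(row["top_score"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# experiment sweeps over nim / top-R / buffer size
# ---------------------------------------------------------------------------


@dataclass
class SweepSpec:
    """Grid for the enrollment-size / voting / buffering experiment.

    The CMC cells use top-R *voting* accuracy (the final prediction is the
    identity most frequent among the top R candidate chips), which is why a
    larger R can slightly lower the value — unlike the rank-based CMC of
    :func:`identification_rates`, which is non-decreasing in R by
    construction.
    """

    nim_values: tuple[int, ...] = (1, 5, 10, 15, 20, 25)
    r_values: tuple[int, ...] = (1, 5, 10)
    buffer_sizes: tuple[int, ...] = (10,)
    probes_per_identity: int = 30
    enroll_pool: int = 40
    diversity_threshold: float = 0.9

    def __post_init__(self) -> None:
        if min(self.nim_values) < 1 or min(self.r_values) < 1 or min(self.buffer_sizes) < 1:
            raise InvalidInputError("sweep grids must be >= 1")
        if self.probes_per_identity <= max(self.buffer_sizes):
            raise InvalidInputError("need more probes per identity than the buffer size")


def _vote_hit(candidates: list[Candidate], truth: str, R: int) -> bool:
    return vote_top_r(candidates, R) == truth


def run_sweep(synth_spec, sweep: SweepSpec | None = None, seed: int | None = None):
    """Build galleries and probe batteries per sweep setting; tabulate results.

    Returns a dict with:

    * ``still`` — DataFrame of voting CMC (%) with one row per nim and one
      column per top R;
    * ``buffered`` — DataFrame indexed by (metric, R) with an unbuffered
      "pipeline" column plus one column per buffer size: CMC (%), #mate ids
      true-positive, #non-mate ids false-positive (all at T = 0);
    * ``eer`` — the still-image EER at nim = max, R = 1.
    """
    from .gallery import EnrollmentConfig, Gallery, enroll
    from .synth import make_identities, sample_embeddings

    sweep = sweep or SweepSpec()
    if seed is None:
        seed = synth_spec.seed
    rng = np.random.default_rng(seed)
    identities = make_identities(synth_spec)
    mates = [i for i in identities if i.is_mate]
    nonmates = [i for i in identities if not i.is_mate]
    if not mates:
        raise InvalidInputError("sweep needs at least one mate identity")

    pools = {m.identity_id: sample_embeddings(m, sweep.enroll_pool, rng) for m in mates}
    probes = {
        ident.identity_id: sample_embeddings(ident, sweep.probes_per_identity, rng)
        for ident in identities
    }

    max_r = max(sweep.r_values)
    still = pd.DataFrame(index=list(sweep.nim_values), columns=list(sweep.r_values), dtype=float)
    still.index.name = "nim"
    buffered_rows = {}
    eer = math.nan

    for nim in sweep.nim_values:
        gal = Gallery()
        cfg = EnrollmentConfig(
            nim_target=nim, diversity_threshold=sweep.diversity_threshold
        )
        for m in mates:
            enroll(gal, m.identity_id, list(pools[m.identity_id]), cfg)

        ranked = {
            ident: [rank(gal, q, max(max_r, 10)) for q in qs]
            for ident, qs in probes.items()
        }
        mate_ids = {m.identity_id for m in mates}

        for R in sweep.r_values:
            if R > nim:  # voting over more candidates than a mate has records
                still.loc[nim, R] = math.nan
                continue
            hits = total = 0
            for m in mates:
                for cands in ranked[m.identity_id]:
                    hits += _vote_hit(cands, m.identity_id, R)
                    total += 1
            still.loc[nim, R] = 100.0 * hits / total

        if nim == max(sweep.nim_values):
            outcomes = []
            for ident_id, per_probe in ranked.items():
                is_mate = ident_id in mate_ids
                for cands in per_probe:
                    outcomes.append(outcome_from_match(ident_id, is_mate, cands))
            grid = np.linspace(-1.0, 1.0, 201)
            eer = det_and_eer(outcomes, grid, R=1).eer_rate

            # buffered comparison at the largest nim, Table-3 style
            from .lookup import apply_threshold
            from .stream import Buffer, buffer_vote

            for R in sweep.r_values:
                pip_ids = {
                    ident: [
                        vote_top_r(cands, R)
                        if apply_threshold(cands, 0.0).accepted
                        else UNIDENTIFIED
                        for cands in per_probe
                    ]
                    for ident, per_probe in ranked.items()
                }
                mate_hits = mate_total = 0
                hit_mate_ids = set()
                for m in mates:
                    for pid in pip_ids[m.identity_id]:
                        mate_hits += pid == m.identity_id
                        mate_total += 1
                        if pid == m.identity_id:
                            hit_mate_ids.add(m.identity_id)
                fp_ids = {
                    pid
                    for n in nonmates
                    for pid in pip_ids[n.identity_id]
                    if pid != UNIDENTIFIED
                }
                buffered_rows[("cmc_pct", R, "pipeline")] = 100.0 * mate_hits / mate_total
                buffered_rows[("n_mate_tp", R, "pipeline")] = len(hit_mate_ids)
                buffered_rows[("n_nonmate_fp", R, "pipeline")] = len(fp_ids)

                for bsize in sweep.buffer_sizes:
                    bh = bt = 0
                    bhit_ids = set()
                    bfp_ids = set()
                    for ident in pip_ids:
                        is_mate = ident in mate_ids
                        buf = Buffer(bsize)
                        for pid in pip_ids[ident]:
                            buf.push(pid)
                            res = buffer_vote(buf)
                            if not res.ready:
                                continue
                            if is_mate:
                                bt += 1
                                if res.buf_id == ident:
                                    bh += 1
                                    bhit_ids.add(ident)
                            elif res.buf_id != UNIDENTIFIED:
                                bfp_ids.add(res.buf_id)
                    buffered_rows[("cmc_pct", R, bsize)] = 100.0 * bh / bt
                    buffered_rows[("n_mate_tp", R, bsize)] = len(bhit_ids)
                    buffered_rows[("n_nonmate_fp", R, bsize)] = len(bfp_ids)

    buffered = pd.Series(buffered_rows).unstack(level=-1)
    buffered.index.names = ["metric", "top_r"]
    cols = ["pipeline"] + [b for b in sweep.buffer_sizes]
    buffered = buffered[cols]
    still.columns.name = "top_r"
    return {"still": still, "buffered": buffered, "eer": eer}
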