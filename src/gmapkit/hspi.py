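"""Hairpin spike-in (HSPI) probe design.

Spike-in controls must hybridize like real shRNA barcode features while not
cross-hybridizing with any of them.  Candidate 21-mers are screened against
the shRNA feature universe by longest shared contiguous identity:

* fewer than ``min_identity`` (13) shared bases with every feature — retained
  without melting-temperature evaluation (unlikely to cross-hybridize);
* more than ``max_identity`` (19) shared bases with any feature — eliminated
  outright;
* otherwise, evaluated: the NN melting temperature of every maximal shared
  segment of length >= ``min_identity`` is computed, and the candidate is
  admissible only if its own perfect-match Tm falls inside the shRNA Tm
  envelope while every cross-segment Tm stays below the envelope minimum.

The top ``n_select`` (200) admissible candidates are chosen by a
deterministic score rewarding both criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from gmapkit.thermo import TmModel, melt_tm

__all__ = [
    "HspiPolicy",
    "CandidateVerdict",
    "longest_common_substring",
    "shared_segments",
    "screen_candidate",
    "select_spike_ins",
    "generate_candidates",
]


@dataclass(frozen=True)
class HspiPolicy:
    """Identity thresholds and selection size for spike-in screening."""

    min_identity: int = 13
    max_identity: int = 19
    n_select: int = 200
    candidate_length: int = 21

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= self.max_identity < self.candidate_length):
            raise ValueError(
                "need 0 < min_identity <= max_identity < candidate_length"
            )


@dataclass
class CandidateVerdict:
    """Screening outcome for one candidate sequence."""

    candidate: str
    status: str  # retained_without_eval | evaluated | eliminated
    max_shared_identity: int
    cross_tm_values: list[float] = field(default_factory=list)
    score: float = float("nan")


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest contiguous substring shared by two sequences."""
    if not a or not b:
        return 0
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def shared_segments(a: str, b: str, min_len: int) -> list[str]:
    """Maximal contiguous substrings shared by ``a`` and ``b`` of length >= min_len.

    A segment is maximal when it cannot be extended on either side at its
    particular alignment; duplicates are removed.
    """
    out: set[str] = set()
    la, lb = len(a), len(b)
    for off in range(-(lb - 1), la):
        run = 0
        # diagonal: positions i in a, i-off in b
        i0 = max(0, off)
        i1 = min(la, lb + off)
        for i in range(i0, i1):
            if a[i] == b[i - off]:
                run += 1
            else:
                if run >= min_len:
                    out.add(a[i - run : i])
                run = 0
        if run >= min_len:
            out.add(a[i1 - run : i1])
    return sorted(out)


def _encode(seqs: Sequence[str], length: int) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), length)
    return arr


def _max_shared_identity_all(candidate: str, features: np.ndarray) -> np.ndarray:
    """Per-feature longest shared run between ``candidate`` and each feature row."""
    lc = len(candidate)
    cand = np.frombuffer(candidate.encode(), dtype="S1")
    n, lf = features.shape
    best = np.zeros(n, dtype=np.int32)
    # run lengths along every alignment diagonal, vectorized across features
    for off in range(-(lf - 1), lc):
        i0, i1 = max(0, off), min(lc, lf + off)
        if i1 - i0 < 1:
            continue
        eq = cand[i0:i1][None, :] == features[:, i0 - off : i1 - off]
        run = np.zeros(n, dtype=np.int32)
        for k in range(eq.shape[1]):
            run = np.where(eq[:, k], run + 1, 0)
            np.maximum(best, run, out=best)
    return best


def screen_candidate(
    candidate: str,
    features: Sequence[str],
    policy: HspiPolicy = HspiPolicy(),
    model: Optional[TmModel] = None,
    _encoded_features: Optional[np.ndarray] = None,
) -> CandidateVerdict:
    """Screen one candidate against the shRNA feature universe."""
    if len(candidate) != policy.candidate_length:
        raise ValueError(
            f"candidate length {len(candidate)} != policy length {policy.candidate_length}"
        )
    if model is None:
        model = TmModel.unified()
    if _encoded_features is None:
        if len(features) == 0:
            return CandidateVerdict(candidate, "retained_without_eval", 0)
        lf = len(features[0])
        _encoded_features = _encode(list(features), lf)
    best = _max_shared_identity_all(candidate, _encoded_features)
    max_id = int(best.max()) if best.size else 0

    if max_id > policy.max_identity:
        return CandidateVerdict(candidate, "eliminated", max_id)
    if max_id < policy.min_identity:
        return CandidateVerdict(candidate, "retained_without_eval", max_id)

    tms: set[float] = set()
    feats = np.asarray(features)
    for idx in np.nonzero(best >= policy.min_identity)[0]:
        for seg in shared_segments(candidate, feats[idx], policy.min_identity):
            tms.add(melt_tm(seg, model))
    return CandidateVerdict(candidate, "evaluated", max_id, sorted(tms))


def select_spike_ins(
    candidates: Sequence[str],
    features: Sequence[str],
    policy: HspiPolicy = HspiPolicy(),
    model: Optional[TmModel] = None,
    shrna_tm_envelope: Optional[tuple[float, float]] = None,
) -> tuple[list[str], list[CandidateVerdict], bool]:
    """Rank and select spike-in sequences.

    Returns ``(selected, verdicts, warning)``; ``warning`` is True when fewer
    admissible candidates survive than ``policy.n_select``.

    The score is the margin by which the envelope minimum clears the
    candidate's highest cross-segment Tm (floored at 0 degC when there are no
    cross segments), minus the distance of the candidate's own perfect-match
    Tm from the envelope midpoint.  Ties break lexicographically on sequence.
    """
    if model is None:
        model = TmModel.unified()
    if shrna_tm_envelope is None:
        if len(features) == 0:
            raise ValueError("need features or an explicit shRNA Tm envelope")
        feat_tms = [melt_tm(f, model) for f in features]
        shrna_tm_envelope = (min(feat_tms), max(feat_tms))
    env_min, env_max = shrna_tm_envelope
    env_mid = 0.5 * (env_min + env_max)

    encoded = None
    if len(features) > 0:
        encoded = _encode(list(features), len(features[0]))

    verdicts: list[CandidateVerdict] = []
    admissible: list[tuple[float, str]] = []
    for cand in candidates:
        v = screen_candidate(cand, features, policy, model, _encoded_features=encoded)
        if v.status != "eliminated":
            pm_tm = melt_tm(cand, model)
            worst_cross = max(v.cross_tm_values) if v.cross_tm_values else 0.0
            v.score = (env_min - worst_cross) - abs(pm_tm - env_mid)
            ok_envelope = env_min <= pm_tm <= env_max
            ok_cross = all(t < env_min for t in v.cross_tm_values)
            if ok_envelope and ok_cross:
                admissible.append((v.score, cand))
        verdicts.append(v)

    admissible.sort(key=lambda t: (-t[0], t[1]))
    selected = [c for _, c in admissible[: policy.n_select]]
    warning = len(selected) < policy.n_select
    return selected, verdicts, warning


def generate_candidates(
    n: int,
    length: int = 21,
    gc_bounds: tuple[float, float] = (0.3, 0.7),
    seed: int | None = None,
) -> list[str]:
    """Seeded uniform random candidate 21-mers with bounded GC fraction."""
    rng = np.random.default_rng(seed)
    lo, hi = gc_bounds
    bases = np.array(list("ACGT"))
    out: list[str] = []
    while len(out) < n:
        block = bases[rng.integers(0, 4, size=(max(64, n), length))]
        gc = ((block == "G") | (block == "C")).mean(axis=1)
        for row, frac in zip(block, gc):
            if lo <= frac <= hi:
                out.append("".join(row))
                if len(out) == n:
                    break
    return out
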