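"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal route available
(full enumeration, straight-line formula transcription) and stay independent
of the library code paths they check.
"""

from __future__ import annotations

import math

import numpy as np

from gmapkit.thermo import load_unified_parameters


def brute_lcs(a: str, b: str) -> int:
    """Longest common substring by enumerating every substring of ``a``."""
    best = 0
    for i in range(len(a)):
        for j in range(i + best + 1, len(a) + 1):
            if a[i:j] in b:
                best = j - i
    return best


def brute_tm(seq: str, strand_conc: float = 50e-9, salt: float = 0.89) -> float:
    """Straight-line NN melting temperature from the shipped parameter JSON."""
    p = load_unified_parameters()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    revcomp = "".join(comp[c] for c in reversed(seq))
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        dh += p["nn_enthalpy"][seq[i : i + 2]]
        ds += p["nn_entropy"][seq[i : i + 2]]
    for term in (seq[0], seq[-1]):
        cls = "GC" if term in "GC" else "AT"
        dh += p["init_enthalpy"][cls]
        ds += p["init_entropy"][cls]
    x = 4.0
    if seq == revcomp:
        x = 1.0
        ds += p["symmetry_entropy"]
    ds += 0.368 * (len(seq) - 1) * math.log(salt)
    return dh * 1000.0 / (ds + 1.987 * math.log(strand_conc / x)) - 273.15


def brute_match_batch(
    reads: list[str],
    sequences: list[str],
    seq_to_ids: dict[str, tuple[str, ...]],
    max_mismatches: int = 1,
    first_base_exact: bool = True,
    compare_length: int = 21,
) -> list[tuple[str, ...]]:
    """All-pairs Hamming scan implementing the matching rules directly.

    A read matches a barcode sequence when the Hamming distance over the
    first ``compare_length`` bases is <= ``max_mismatches`` and (optionally)
    the first bases agree; the read is assigned to the unique minimal-
    distance sequence's IDs, or to nothing on a tie between distinct
    sequences.  Sequences duplicated under several IDs count as one
    sequence.
    """
    sequences = sorted({s[:compare_length] for s in sequences})
    lib = np.frombuffer("".join(sequences).encode(), dtype="S1")
    lib = lib.reshape(len(sequences), compare_length)
    out: list[tuple[str, ...]] = []
    for chunk_start in range(0, len(reads), 1000):
        chunk = reads[chunk_start : chunk_start + 1000]
        enc = np.frombuffer(
            "".join(r[:compare_length] for r in chunk).encode(), dtype="S1"
        ).reshape(len(chunk), compare_length)
        d = (enc[:, None, :] != lib[None, :, :]).sum(axis=2)
        ok = d <= max_mismatches
        if first_base_exact:
            ok &= enc[:, 0][:, None] == lib[None, :, 0]
        for r in range(len(chunk)):
            cand = np.nonzero(ok[r])[0]
            if cand.size == 0:
                out.append(())
                continue
            dmin = d[r, cand].min()
            winners = cand[d[r, cand] == dmin]
            if len(winners) != 1:
                out.append(())
            else:
                out.append(seq_to_ids[sequences[winners[0]][:compare_length]])
    return out
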