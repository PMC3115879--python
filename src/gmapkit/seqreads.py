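"""Sequencing read-out for pooled barcode screens.

Reads are 22-base single-end sequences primed immediately upstream of the
21-nt shRNA sense stem.  A read is assigned to a barcode when the Hamming
distance over the first 21 bases is at most one mismatch, with the first
nucleotide required to match exactly.  Reads equidistant from two distinct
barcode sequences are discarded as ambiguous; reads matching a sequence that
is duplicated under several barcode IDs are credited once to every ID.

Also builds the synthetic reference chromosome (barcode stems interleaved
with 79-nt random spacers) used by alignment-based workflows, and the
per-run count summaries (quartiles, uncounted barcodes, unmapped fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from gmapkit.arrays import round_percent
from gmapkit.manifest import BarcodeLibrary

__all__ = [
    "ChromosomeLayout",
    "MatcherPolicy",
    "SeqRunSummary",
    "BarcodeIndex",
    "build_synthetic_chromosome",
    "write_chromosome_fasta",
    "match_read",
    "count_reads",
    "log2_counts",
    "detection_accounting",
]


@dataclass
class ChromosomeLayout:
    """Layout of the synthetic reference: barcode offsets and spacer length."""

    spacer_length: int
    rng_seed: Optional[int]
    offsets: dict[str, int]


@dataclass(frozen=True)
class MatcherPolicy:
    """Read-to-barcode matching rules."""

    read_length: int = 22
    compare_length: int = 21
    max_mismatches: int = 1
    first_base_exact: bool = True
    #: also try the reverse complement of each read; off by default because
    #: reads are primed from a fixed strand
    try_reverse_complement: bool = False

    def __post_init__(self) -> None:
        if self.compare_length > self.read_length:
            raise ValueError("compare_length must be <= read_length")
        if self.max_mismatches >= self.compare_length:
            raise ValueError("max_mismatches must be < compare_length")


@dataclass
class SeqRunSummary:
    """Per-run sequencing summary (counts and per-barcode statistics)."""

    reads_passed_filter: int
    mapped_reads: int
    unmapped_reads: int
    unmapped_pct: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    uncounted: int

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Reads passed filter": self.reads_passed_filter,
                "Mapped reads": self.mapped_reads,
                "Unmapped reads": self.unmapped_reads,
                "Unmapped reads %": self.unmapped_pct,
                "1st quartile": self.q1,
                "Median": self.median,
                "Mean": self.mean,
                "3rd quartile": self.q3,
                "Max": self.max,
                "Uncounted": self.uncounted,
            }
        )


def unmapped_percent(reads_passed_filter: int, unmapped: int) -> float:
    """Unmapped-read percentage, rounded half-even to two decimals."""
    if reads_passed_filter <= 0:
        raise ValueError("reads_passed_filter must be positive")
    return round_percent(100.0 * unmapped / reads_passed_filter)


def build_synthetic_chromosome(
    library: BarcodeLibrary, spacer_length: int = 79, seed: Optional[int] = None
) -> tuple[str, ChromosomeLayout]:
    """Interleave barcode stems with random spacers into one reference sequence.

    Layout: spacer + (barcode + spacer) per library entry, so n barcodes of
    21 nt give a sequence of n*21 + (n+1)*79 bases.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def spacer() -> str:
        return "".join(bases[rng.integers(0, 4, size=spacer_length)])

    parts = [spacer()]
    offsets: dict[str, int] = {}
    pos = spacer_length
    for bc_id, seq in zip(
        library.records["barcode_id"], library.records["sequence"]
    ):
        offsets[bc_id] = pos
        parts.append(seq)
        parts.append(spacer())
        pos += len(seq) + spacer_length
    return "".join(parts), ChromosomeLayout(spacer_length, seed, offsets)


def write_chromosome_fasta(
    sequence: str, path: str | Path, name: str = "synthetic_chromosome"
) -> None:
    """Write the synthetic reference as a single-record FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


class BarcodeIndex:
    """Exact + one-mismatch lookup index over a barcode library.

    Maps each distinct sense sequence to all barcode IDs carrying it
    (duplicated sequences map to several IDs).
    """

    def __init__(self, library: BarcodeLibrary, policy: MatcherPolicy = MatcherPolicy()):
        self.policy = policy
        self.library = library
        self.seq_to_ids: dict[str, tuple[str, ...]] = {}
        for bc_id, seq in zip(
            library.records["barcode_id"], library.records["sequence"]
        ):
            key = seq[: policy.compare_length]
            self.seq_to_ids.setdefault(key, ())
            self.seq_to_ids[key] += (bc_id,)

    def lookup(self, prefix: str) -> Optional[tuple[str, ...]]:
        return self.seq_to_ids.get(prefix)


def _neighbor_match(index: BarcodeIndex, prefix: str) -> tuple[str, ...]:
    """One-mismatch lookup respecting the first-base rule; ambiguous -> empty."""
    policy = index.policy
    start = 1 if policy.first_base_exact else 0
    hit_seqs: set[str] = set()
    chars = "ACGT"
    for pos in range(start, policy.compare_length):
        orig = prefix[pos]
        for alt in chars:
            if alt == orig:
                continue
            variant = prefix[:pos] + alt + prefix[pos + 1 :]
            if variant in index.seq_to_ids:
                hit_seqs.add(variant)
    if len(hit_seqs) != 1:
        return ()
    return index.seq_to_ids[hit_seqs.pop()]


def match_read(
    read: str, index: BarcodeIndex, policy: Optional[MatcherPolicy] = None
) -> tuple[str, ...]:
    """Barcode IDs a read is assigned to (empty tuple when unassigned).

    Rules: Hamming distance over the first ``compare_length`` bases at most
    ``max_mismatches``; first base must agree exactly when
    ``first_base_exact``; ties between distinct barcode sequences at minimal
    distance are ambiguous and return empty; a duplicated sequence returns
    all its IDs.
    """
    policy = policy or index.policy
    if len(read) < policy.compare_length:
        return ()
    ids = _match_forward(read, index, policy)
    if not ids and policy.try_reverse_complement:
        from gmapkit.thermo import reverse_complement

        ids = _match_forward(reverse_complement(read), index, policy)
    return ids


def _match_forward(
    read: str, index: BarcodeIndex, policy: MatcherPolicy
) -> tuple[str, ...]:
    prefix = read[: policy.compare_length]
    exact = index.lookup(prefix)
    if exact is not None:
        return exact
    if policy.max_mismatches == 0:
        return ()
    if policy.max_mismatches == 1:
        return _neighbor_match(index, prefix)
    # generic fallback for larger mismatch budgets: scan all sequences
    best_d = policy.max_mismatches + 1
    best_seqs: list[str] = []
    start = 1 if policy.first_base_exact else 0
    for seq in index.seq_to_ids:
        if policy.first_base_exact and seq[0] != prefix[0]:
            continue
        d = sum(a != b for a, b in zip(prefix[start:], seq[start:]))
        if d < best_d:
            best_d, best_seqs = d, [seq]
        elif d == best_d:
            best_seqs.append(seq)
    if best_d <= policy.max_mismatches and len(best_seqs) == 1:
        return index.seq_to_ids[best_seqs[0]]
    return ()


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title, seq


def count_reads(
    reads: str | Path | Iterable[str],
    library: BarcodeLibrary,
    policy: MatcherPolicy = MatcherPolicy(),
) -> tuple[pd.Series, SeqRunSummary]:
    """Assign reads to barcodes and summarize the run.

    ``reads`` is a FASTQ path (optionally gzipped) or an iterable of read
    sequences.  Returns a per-barcode count table (every library ID present,
    zeros included) and a :class:`SeqRunSummary`.  Quartiles and the mean
    are computed over barcodes with at least one assigned read, quartiles by
    linear interpolation.
    """
    if isinstance(reads, (str, Path)):
        seq_iter: Iterable[str] = (seq for _, seq in _iter_fastq(reads))
    else:
        seq_iter = reads

    index = BarcodeIndex(library, policy)
    counts: dict[str, int] = {bc: 0 for bc in library.barcode_ids}
    total = 0
    mapped = 0
    for seq in seq_iter:
        total += 1
        ids = match_read(seq, index, policy)
        if ids:
            mapped += 1
            for bc in ids:
                counts[bc] += 1

    table = pd.Series(counts, name="count").astype(int)
    nonzero = table[table > 0].to_numpy(dtype=float)
    if nonzero.size:
        q1, med, q3 = np.percentile(nonzero, [25, 50, 75])
        mean = float(nonzero.mean())
        mx = float(nonzero.max())
    else:
        q1 = med = q3 = mean = mx = 0.0
    unmapped = total - mapped
    summary = SeqRunSummary(
        reads_passed_filter=total,
        mapped_reads=mapped,
        unmapped_reads=unmapped,
        unmapped_pct=unmapped_percent(total, unmapped) if total else 0.0,
        q1=float(q1),
        median=float(med),
        mean=mean,
        q3=float(q3),
        max=mx,
        uncounted=int((table == 0).sum()),
    )
    return table, summary


def log2_counts(
    counts: pd.Series, min_reads: int = 16, pseudocount: float = 0.0
) -> tuple[pd.Series, list[str]]:
    """Log2-transform read counts, dropping barcodes below ``min_reads``.

    Returns the log2 table and the list of dropped barcode IDs.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = counts[counts >= min_reads]
    dropped = sorted(counts.index.difference(keep.index))
    vals = np.log2(keep.to_numpy(dtype=float) + pseudocount)
    return pd.Series(vals, index=keep.index, name="log2_count"), dropped


def detection_accounting(
    n_ids: int, n_duplicated_sequences: int, n_detected_distinct: int
) -> tuple[int, float]:
    """Detected fraction of distinct expected barcode sequences.

    The expected denominator counts distinct sequences: total IDs minus the
    number of sequences duplicated across IDs.  Returns
    ``(n_distinct_expected, percent_detected)`` with the percentage rounded
    to one decimal.
    """
    n_distinct_expected = n_ids - n_duplicated_sequences
    if n_distinct_expected <= 0:
        raise ValueError("no distinct sequences expected")
    if n_detected_distinct > n_distinct_expected:
        raise ValueError("detected more sequences than expected")
    percent = float(np.round(100.0 * n_detected_distinct / n_distinct_expected, 1))
    return n_distinct_expected, percent
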