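"""Chip-manifest model: probe classes, feature records, barcode libraries.

The detection array carries several probe classes — 22-mer shRNA barcode
features in triplicate (HP), negative and mismatch controls (HPC, HPTMM),
hairpin spike-ins in 25 clusters of 200 (HSPI), yeast barcode and ORF
features (TAG, yORF), human ORF features (hORF, huORF), and GC-background
probes (GCBG) used to estimate non-specific binding.  The manifest records
the per-class catalogue (unique probes x replicates) and, when sequences are
available, per-feature GC metadata used downstream by background correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

_VALID_BASES = frozenset("ACGT")

#: Probe-class catalogue of the 1.06M-feature array (UT GMAP 1.0).
#: GC-background probes are not part of the published catalogue table; they
#: are carried as an extra configurable class (default 33,894 probes).
GMAP_CLASS_SPECS: tuple["ProbeClassSpec", ...]


@dataclass(frozen=True)
class ProbeClassSpec:
    """Catalogue entry for one probe class.

    Parameters
    ----------
    class_id
        Short label, e.g. ``"HP"`` for shRNA barcode features.
    description
        Free-text description.
    unique_probes
        Number of distinct probe sequences in the class.
    replicates
        Identical replicate features per unique probe.
    probe_length
        Probe length in bases.
    """

    class_id: str
    description: str
    unique_probes: int
    replicates: int
    probe_length: int

    def __post_init__(self) -> None:
        if self.unique_probes < 0:
            raise ValueError(f"{self.class_id}: unique_probes must be >= 0")
        if self.replicates < 1:
            raise ValueError(f"{self.class_id}: replicates must be >= 1")
        if self.probe_length <= 0:
            raise ValueError(f"{self.class_id}: probe_length must be > 0")

    @property
    def total_probes(self) -> int:
        return self.unique_probes * self.replicates


GMAP_CLASS_SPECS = (
    ProbeClassSpec("hORF", "Human ORFeome", 134901, 1, 25),
    ProbeClassSpec("huORF", "HuGene ORFs", 58087, 1, 25),
    ProbeClassSpec("HP", "shRNA sequences (mouse and human)", 248049, 3, 22),
    ProbeClassSpec("HPC", "shRNA negative controls", 138, 33, 22),
    ProbeClassSpec("HSPI", "Hybridization spike-in probes", 200, 25, 22),
    ProbeClassSpec("HPTMM", "shRNA mismatch control probes", 8097, 3, 22),
    ProbeClassSpec("TAG", "Yeast barcode probes", 26801, 3, 20),
    ProbeClassSpec("yORF", "Yeast open reading frames", 11421, 1, 25),
)

#: Default number of GC-background probes on the array.
N_GCBG_DEFAULT = 33894


def gcbg_class_spec(n_probes: int = N_GCBG_DEFAULT) -> ProbeClassSpec:
    """Spec for the GC-background probe class (configurable count)."""
    return ProbeClassSpec("GCBG", "GC-background probes", n_probes, 1, 25)


@dataclass
class BarcodeLibrary:
    """Barcode IDs with their 21-nt sense sequences.

    ``duplicated_sequences`` is the set of sequences shared by two or more
    distinct barcode IDs — reads matching such a sequence are credited once
    to every ID that carries it.
    """

    records: pd.DataFrame  # columns: barcode_id, sequence, annotation
    duplicated_sequences: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        required = {"barcode_id", "sequence"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"library table needs columns {sorted(required)}")
        if "annotation" not in self.records.columns:
            self.records = self.records.assign(annotation="")
        bad = self.records["sequence"].str.len() != 21
        if bad.any():
            offender = self.records.loc[bad, "barcode_id"].iloc[0]
            raise ValueError(f"sense sequence of {offender!r} is not 21 nt")
        if self.records["barcode_id"].duplicated().any():
            raise ValueError("barcode_id values must be unique")
        counts = self.records["sequence"].value_counts()
        self.duplicated_sequences = frozenset(counts.index[counts >= 2])

    def __len__(self) -> int:
        return len(self.records)

    @property
    def barcode_ids(self) -> list[str]:
        return self.records["barcode_id"].tolist()

    @property
    def n_distinct_sequences(self) -> int:
        return self.records["sequence"].nunique()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeLibrary":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        cols = {c.lower(): c for c in df.columns}
        rename = {}
        for want in ("barcode_id", "sequence", "annotation"):
            if want in cols:
                rename[cols[want]] = want
        df = df.rename(columns=rename)
        return cls(records=df)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "BarcodeLibrary":
        from Bio import SeqIO

        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(records=pd.DataFrame({"barcode_id": ids, "sequence": seqs}))

    @classmethod
    def from_file(cls, path: str | Path) -> "BarcodeLibrary":
        path = Path(path)
        if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
            return cls.from_fasta(path)
        return cls.from_tsv(path)


@dataclass
class ChipManifest:
    """Ordered probe-class catalogue plus the feature-level table.

    ``features`` has one row per physical feature with columns
    ``feature_id, class_id, barcode_id, replicate_index, sequence, gc_count``.
    """

    classes: list[ProbeClassSpec]
    features: pd.DataFrame

    @property
    def total_features(self) -> int:
        return int(len(self.features))

    @property
    def total_unique(self) -> int:
        return int(sum(c.unique_probes for c in self.classes))

    def class_summary(self) -> pd.DataFrame:
        """Per-class catalogue mirroring the published feature table."""
        rows = [
            {
                "class_id": c.class_id,
                "description": c.description,
                "unique_probes": c.unique_probes,
                "replicates": c.replicates,
                "total_probes": c.total_probes,
                "probe_length": c.probe_length,
            }
            for c in self.classes
        ]
        return pd.DataFrame(rows)

    def class_totals(self) -> dict[str, int]:
        return {c.class_id: c.total_probes for c in self.classes}


def gc_count(sequence: str) -> int:
    """Number of G or C characters in an ACGT sequence."""
    seq = sequence.upper()
    if not _VALID_BASES.issuperset(seq):
        bad = sorted(set(seq) - _VALID_BASES)
        raise ValueError(f"non-ACGT character(s) {bad} in sequence")
    return seq.count("G") + seq.count("C")


def derive_feature_sequence(
    stem_21nt: str, extension_base: str, end: str = "three_prime"
) -> str:
    """Extend a 21-nt barcode stem to the 22-nt feature sequence.

    The array's shRNA features are the 21-base stem plus one extra stem base;
    which end receives it is a design choice exposed via ``end``
    (``"three_prime"`` appends, ``"five_prime"`` prepends).
    """
    stem = stem_21nt.upper()
    if len(stem) != 21:
        raise ValueError(f"stem must be 21 nt, got {len(stem)}")
    if not _VALID_BASES.issuperset(stem):
        raise ValueError("stem contains non-ACGT characters")
    base = extension_base.upper()
    if base not in _VALID_BASES:
        raise ValueError(f"extension base must be one of ACGT, got {extension_base!r}")
    if end == "three_prime":
        return stem + base
    if end == "five_prime":
        return base + stem
    raise ValueError("end must be 'three_prime' or 'five_prime'")


def feature_area_ratio(side_a: float, side_b: float) -> float:
    """Surface-area ratio of two square features with the given side lengths (um)."""
    if side_a <= 0 or side_b <= 0:
        raise ValueError("feature side lengths must be positive")
    return (side_a / side_b) ** 2


def build_manifest(
    class_specs: Sequence[ProbeClassSpec],
    library: Optional[BarcodeLibrary] = None,
    barcode_class: str = "HP",
    seed: Optional[int] = None,
) -> ChipManifest:
    """Assemble a chip manifest from probe-class specs.

    When a :class:`BarcodeLibrary` is supplied, the ``barcode_class`` entries
    are derived from it (the class's ``unique_probes`` is replaced by the
    library size and each feature carries the 22-nt sequence extended from
    the 21-nt stem).  When a ``seed`` is supplied, probe classes without
    sequences (controls, GC-background) receive random sequences of the
    class's probe length so GC metadata is available downstream.
    """
    specs = list(class_specs)
    seen: set[str] = set()
    for spec in specs:
        if spec.class_id in seen:
            raise ValueError(f"duplicate probe class {spec.class_id!r}")
        seen.add(spec.class_id)

    rng = np.random.default_rng(seed) if seed is not None else None
    bases = np.frombuffer(b"ACGT", dtype="S1")
    frames: list[pd.DataFrame] = []
    for spec in specs:
        if spec.unique_probes == 0:
            continue
        if library is not None and spec.class_id == barcode_class:
            stems = library.records["sequence"].to_numpy()
            ids = library.records["barcode_id"].to_numpy()
            n = len(stems)
            # extend each stem at the 3' end with its own first base as the
            # caller-independent stand-in for the next hairpin-stem base
            seqs = np.array([derive_feature_sequence(s, s[0]) for s in stems])
            gc = np.array([gc_count(s) for s in seqs])
            rep = np.tile(np.arange(1, spec.replicates + 1), n)
            frames.append(
                pd.DataFrame(
                    {
                        "class_id": spec.class_id,
                        "barcode_id": np.repeat(ids, spec.replicates),
                        "replicate_index": rep,
                        "sequence": np.repeat(seqs, spec.replicates),
                        "gc_count": np.repeat(gc, spec.replicates),
                    }
                )
            )
        else:
            n = spec.unique_probes
            if rng is not None:
                mat = bases[rng.integers(0, 4, size=(n, spec.probe_length))]
                seqs = mat.view(f"S{spec.probe_length}").ravel().astype(str)
                gc = np.char.count(seqs, "G") + np.char.count(seqs, "C")
            else:
                seqs = np.full(n, "", dtype=object)
                gc = np.full(n, -1)
            rep = np.tile(np.arange(1, spec.replicates + 1), n)
            frames.append(
                pd.DataFrame(
                    {
                        "class_id": spec.class_id,
                        "barcode_id": "",
                        "replicate_index": rep,
                        "sequence": np.repeat(seqs, spec.replicates),
                        "gc_count": np.repeat(gc, spec.replicates),
                    }
                )
            )

    if frames:
        features = pd.concat(frames, ignore_index=True)
    else:
        features = pd.DataFrame(
            columns=["class_id", "barcode_id", "replicate_index", "sequence", "gc_count"]
        )
    features.insert(0, "feature_id", [f"F{i:07d}" for i in range(len(features))])

    # adjust specs whose counts were overridden by the library
    if library is not None:
        specs = [
            ProbeClassSpec(
                s.class_id, s.description, len(library), s.replicates, s.probe_length
            )
            if s.class_id == barcode_class
            else s
            for s in specs
        ]
    return ChipManifest(classes=specs, features=features)


def write_manifest(
    manifest: ChipManifest, feature_path: str | Path, summary_path: str | Path
) -> None:
    """Write the feature-level and class-summary TSVs."""
    manifest.features.to_csv(feature_path, sep="\t", index=False)
    manifest.class_summary().to_csv(summary_path, sep="\t", index=False)
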