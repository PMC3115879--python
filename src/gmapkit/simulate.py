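"""Simulator for pooled-screen dilution experiments.

Regenerates the study designs used to validate the platform: an even
reference pool plus dilution pools in which sub-fractions of barcodes are
reduced 4/16/64-fold (separate pools) or 2/5/10/20-fold (one mixed pool),
and a ~90k-scale reference/dilution pair.  Downstream read-outs are modeled
as (i) a saturating array-signal response with lognormal noise, reproducing
the observed compression of diluted subpools on the array, and (ii)
multinomial sequencing reads with substitution errors, which stay linear in
concentration.  An optional infection bottleneck (Poisson total at a given
MOI, multinomial allocation) emulates the lentiviral transduction step.

All simulators are deterministic given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from gmapkit.manifest import BarcodeLibrary, ChipManifest

__all__ = [
    "PoolDesign",
    "ArraySignalModel",
    "InfectionModel",
    "DesignSpec",
    "make_library",
    "make_pool_design",
    "simulate_infection",
    "simulate_array_signal",
    "simulate_reads",
    "BUILTIN_DESIGNS",
]


@dataclass
class PoolDesign:
    """Relative concentration and subpool label per barcode."""

    concentrations: pd.Series  # barcode_id -> relative concentration
    subpool_labels: pd.Series  # barcode_id -> label
    design_name: str = "custom"

    def __post_init__(self) -> None:
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be positive")
        if not self.concentrations.index.equals(self.subpool_labels.index):
            raise ValueError("labels must cover exactly the designed barcodes")

    @property
    def total_mass(self) -> float:
        return float(self.concentrations.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode_id": self.concentrations.index,
                "concentration": self.concentrations.to_numpy(),
                "subpool_label": self.subpool_labels.to_numpy(),
            }
        )


@dataclass(frozen=True)
class ArraySignalModel:
    """Saturating intensity response: I = B + A*c/(c+K), lognormal noise.

    ``noise_sd`` is the SD of the per-feature noise on the log2 scale;
    features whose barcode is absent from the pool (c = 0) read B plus noise.
    """

    amplitude: float = 30000.0
    half_saturation: float = 1.0
    background: float = 120.0
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.half_saturation <= 0:
            raise ValueError("amplitude and half_saturation must be > 0")
        if self.background < 0 or self.noise_sd < 0:
            raise ValueError("background and noise_sd must be >= 0")


@dataclass(frozen=True)
class InfectionModel:
    """Lentiviral bottleneck: Poisson total integrations at n_cells * moi."""

    n_cells: int = 70_000_000
    moi: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.moi <= 0:
            raise ValueError("n_cells and moi must be positive")


@dataclass(frozen=True)
class DesignSpec:
    """Parameters for a named pool design.

    ``dilutions`` maps subpool label -> dilution factor; ``subset_fraction``
    is the fraction of the library placed in each diluted subset (sizes are
    rounded).  The undiluted remainder carries ``bulk_label``.
    """

    name: str
    dilutions: tuple[tuple[str, float], ...] = ()
    subset_fraction: float = 0.0
    bulk_label: str = "1x"


#: Built-in designs, subset fractions scaled from the study's pool layouts
#: (~8,300 or ~8,400 of 78,432 barcodes; ~3,500 of 90,408).
BUILTIN_DESIGNS: dict[str, DesignSpec] = {
    "even_78k": DesignSpec("even_78k"),
    "dil_4x": DesignSpec("dil_4x", (("4x", 4.0),), 8300 / 78432),
    "dil_16x": DesignSpec("dil_16x", (("16x", 16.0),), 8300 / 78432),
    "dil_64x": DesignSpec("dil_64x", (("64x", 64.0),), 8300 / 78432),
    "mix_2_5_10_20": DesignSpec(
        "mix_2_5_10_20",
        (("2x", 2.0), ("5x", 5.0), ("10x", 10.0), ("20x", 20.0)),
        8400 / 78432,
    ),
    "ref_90k": DesignSpec("ref_90k"),
    "dil_90k": DesignSpec(
        "dil_90k",
        (("2x", 2.0), ("5x", 5.0), ("10x", 10.0), ("20x", 20.0)),
        3500 / 90408,
    ),
}


def make_library(
    n_barcodes: int = 5000,
    n_duplicated: int = 0,
    seed: int = 0,
    prefix: str = "BC",
) -> BarcodeLibrary:
    """Random 21-nt barcode library, optionally with duplicated sequences.

    ``n_duplicated`` sequences are each assigned to a second barcode ID,
    emulating sequences shared by multiple hairpin clones.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    n_unique = n_barcodes - n_duplicated
    if n_unique <= 0:
        raise ValueError("n_duplicated must be smaller than n_barcodes")
    seqs: set[str] = set()
    while len(seqs) < n_unique:
        block = bases[rng.integers(0, 4, size=(n_unique - len(seqs) + 16, 21))]
        for row in block:
            seqs.add("".join(row))
            if len(seqs) == n_unique:
                break
    unique = sorted(seqs)
    rng.shuffle(unique)
    all_seqs = unique + unique[:n_duplicated]
    ids = [f"{prefix}{i:06d}" for i in range(len(all_seqs))]
    return BarcodeLibrary(
        records=pd.DataFrame({"barcode_id": ids, "sequence": all_seqs})
    )


def make_pool_design(
    library: BarcodeLibrary,
    design_spec: DesignSpec | str,
    seed: int = 0,
) -> PoolDesign:
    """Assign relative concentrations per the design: bulk at 1, subsets at 1/d.

    Subsets are drawn without replacement (seeded) and never overlap.
    """
    if isinstance(design_spec, str):
        design_spec = BUILTIN_DESIGNS[design_spec]
    ids = np.array(library.barcode_ids)
    n = len(ids)
    subset_size = int(round(design_spec.subset_fraction * n))
    n_subsets = len(design_spec.dilutions)
    if n_subsets * subset_size > n:
        raise ValueError("diluted subsets exceed library size")
    for _, d in design_spec.dilutions:
        if d < 1:
            raise ValueError("dilution factors must be >= 1")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    conc = pd.Series(1.0, index=ids)
    labels = pd.Series(design_spec.bulk_label, index=ids)
    for k, (label, d) in enumerate(design_spec.dilutions):
        members = ids[order[k * subset_size : (k + 1) * subset_size]]
        conc.loc[members] = 1.0 / d
        labels.loc[members] = label
    return PoolDesign(conc, labels, design_spec.name)


def simulate_infection(
    design: PoolDesign, model: InfectionModel = InfectionModel()
) -> pd.Series:
    """Integrated lentiviral copies per barcode after the infection bottleneck."""
    rng = np.random.default_rng(model.seed)
    total = int(rng.poisson(model.n_cells * model.moi))
    probs = (design.concentrations / design.total_mass).to_numpy()
    counts = rng.multinomial(total, probs)
    return pd.Series(counts, index=design.concentrations.index, name="copies")


def simulate_array_signal(
    abundances: pd.Series,
    model: ArraySignalModel,
    manifest: ChipManifest,
    array_id: str = "array",
) -> pd.DataFrame:
    """Per-feature intensities for one hybridization.

    Every manifest feature gets intensity ``B + A*c/(c+K)`` for its linked
    barcode's relative abundance c (0 for off-pool and non-barcode features),
    multiplied by lognormal noise with log2-scale SD ``noise_sd``,
    independently per replicate feature.
    """
    if (abundances < 0).any():
        raise ValueError("abundances must be >= 0")
    feats = manifest.features
    conc = feats["barcode_id"].map(abundances).fillna(0.0).to_numpy(dtype=float)
    clean = model.background + model.amplitude * conc / (conc + model.half_saturation)
    rng = np.random.default_rng(model.seed)
    if model.noise_sd > 0:
        noise = np.exp(rng.normal(0.0, model.noise_sd * np.log(2.0), size=len(feats)))
    else:
        noise = 1.0
    out = feats[["feature_id", "class_id", "barcode_id", "replicate_index", "gc_count"]].copy()
    out["intensity"] = clean * noise
    out["array_id"] = array_id
    return out


_READ_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_reads(
    abundances: pd.Series,
    library: BarcodeLibrary,
    total_reads: int,
    error_rate: float = 0.001,
    seed: int = 0,
    fastq_path: Optional[str | Path] = None,
    layout_base: str = "A",
) -> tuple[list[str] | None, pd.Series]:
    """Multinomial sequencing reads over barcodes, with substitution errors.

    Each read is a barcode's 21-nt stem plus one trailing layout base
    (22-base reads); per-base substitution errors occur at ``error_rate``.
    Returns ``(reads, truth_counts)``; when ``fastq_path`` is given the reads
    are streamed to that FASTQ file (constant quality line) and ``None`` is
    returned in their place.  ``abundances`` is indexed like the library and
    may be a pool design's concentrations or infection copy numbers.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not (0 <= error_rate < 0.25):
        raise ValueError("error_rate must be in [0, 0.25)")
    ab = abundances.reindex(library.barcode_ids).fillna(0.0)
    probs = (ab / ab.sum()).to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    truth = rng.multinomial(total_reads, probs)
    truth_counts = pd.Series(truth, index=library.barcode_ids, name="count")

    # expand to per-read barcode rows, mutate with vectorized substitutions
    seqs = library.records["sequence"].to_numpy()
    code_lut = np.zeros(128, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        code_lut[ord(b)] = i
    stem_codes = np.array(
        [code_lut[np.frombuffer((s + layout_base).encode(), dtype=np.uint8)] for s in seqs],
        dtype=np.uint8,
    )
    read_idx = np.repeat(np.arange(len(seqs)), truth)
    rng.shuffle(read_idx)
    mat = stem_codes[read_idx]  # (total_reads, 22)
    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        mat[err] = (mat[err] + shift) % 4
    read_bytes = _READ_BASES[mat].view(f"S{mat.shape[1]}").ravel()

    if fastq_path is not None:
        qual = "I" * mat.shape[1]
        with open(fastq_path, "w") as fh:
            chunk: list[str] = []
            for i, rb in enumerate(read_bytes):
                chunk.append(f"@read{i}\n{rb.decode()}\n+\n{qual}")
                if len(chunk) == 100_000:
                    fh.write("\n".join(chunk) + "\n")
                    chunk = []
            if chunk:
                fh.write("\n".join(chunk) + "\n")
        return None, truth_counts
    return [rb.decode() for rb in read_bytes], truth_counts
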