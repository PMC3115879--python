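"""Nearest-neighbor melting-temperature model for short DNA duplexes.

Implements the two-state nearest-neighbor model with the unified
perfect-match dinucleotide parameter set:

    Tm(K) = dH / (dS_salt + R ln(C_T / x))

where dH and dS are sums of dinucleotide stacking terms plus duplex
initiation terms, x is 4 for non-self-complementary duplexes (1 for
self-complementary, with an extra symmetry entropy term), and the
monovalent-salt entropy correction is

    dS_salt = dS + 0.368 * N * ln[Na+]

with N the number of phosphates divided by 2 (= duplex length - 1).
The parameter table ships as a JSON data file so that independent
re-implementations can load the identical constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

R_GAS = 1.987  # cal/(mol K)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_unified_parameters() -> dict:
    """Load the shipped unified NN parameter table (JSON)."""
    with resources.files("gmapkit.data").joinpath("nn_unified.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class TmModel:
    """Nearest-neighbor duplex stability model.

    Parameters
    ----------
    nn_enthalpy, nn_entropy
        Per-dinucleotide stacking terms (kcal/mol and cal/(mol K)),
        keyed by the 5'->3' top-strand dinucleotide.
    init_enthalpy, init_entropy
        Duplex initiation terms keyed by terminal base-pair class
        ("GC" or "AT").
    symmetry_entropy
        Extra entropy for self-complementary duplexes (cal/(mol K)).
    strand_concentration
        Total single-strand concentration C_T in mol/L (default 50 nM).
    salt_concentration
        Monovalent cation concentration in mol/L.  Default 0.89 M, the
        NaCl concentration of the array hybridization buffer.
    """

    nn_enthalpy: Mapping[str, float]
    nn_entropy: Mapping[str, float]
    init_enthalpy: Mapping[str, float]
    init_entropy: Mapping[str, float]
    symmetry_entropy: float = -1.4
    strand_concentration: float = 50e-9
    salt_concentration: float = 0.89

    def __post_init__(self) -> None:
        dinucs = {a + b for a in "ACGT" for b in "ACGT"}
        missing = dinucs - set(self.nn_enthalpy) | dinucs - set(self.nn_entropy)
        if missing:
            raise ValueError(f"NN table missing dinucleotides: {sorted(missing)}")
        if self.strand_concentration <= 0 or self.salt_concentration <= 0:
            raise ValueError("concentrations must be positive")

    @classmethod
    def unified(cls, **overrides) -> "TmModel":
        """Model using the shipped unified parameter table."""
        p = load_unified_parameters()
        return cls(
            nn_enthalpy=p["nn_enthalpy"],
            nn_entropy=p["nn_entropy"],
            init_enthalpy=p["init_enthalpy"],
            init_entropy=p["init_entropy"],
            symmetry_entropy=p["symmetry_entropy"],
            **overrides,
        )


def _terminal_class(base: str) -> str:
    return "GC" if base in "GC" else "AT"


def melt_tm(duplex: str, model: TmModel | None = None) -> float:
    """Perfect-match melting temperature (degrees C) of a DNA duplex.

    ``duplex`` is the 5'->3' sequence of one strand; the other strand is its
    perfect complement.  Deterministic for a fixed model.
    """
    if model is None:
        model = TmModel.unified()
    seq = duplex.upper()
    if len(seq) < 2:
        raise ValueError("duplex must be at least 2 nt")
    if not set(seq) <= set("ACGT"):
        raise ValueError("duplex contains non-ACGT characters")

    dh = model.init_enthalpy[_terminal_class(seq[0])] + model.init_enthalpy[
        _terminal_class(seq[-1])
    ]
    ds = model.init_entropy[_terminal_class(seq[0])] + model.init_entropy[
        _terminal_class(seq[-1])
    ]
    for i in range(len(seq) - 1):
        dd = seq[i : i + 2]
        dh += model.nn_enthalpy[dd]
        ds += model.nn_entropy[dd]

    self_comp = seq == reverse_complement(seq)
    x = 1.0 if self_comp else 4.0
    if self_comp:
        ds += model.symmetry_entropy

    # salt correction on entropy; N = number of phosphates / 2
    ds_salt = ds + 0.368 * (len(seq) - 1) * math.log(model.salt_concentration)
    tm_k = (dh * 1000.0) / (ds_salt + R_GAS * math.log(model.strand_concentration / x))
    return tm_k - 273.15
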