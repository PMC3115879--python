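{
  "comment": "Unified nearest-neighbor parameters for DNA/DNA perfect-match duplexes (SantaLucia 1998 unified set). Enthalpy kcal/mol, entropy cal/(mol K). Keys are 5'->3' top-strand dinucleotides; initiation terms depend on the terminal base pair.",
  "nn_enthalpy": {
    "AA": -7.9, "TT": -7.9,
    "AT": -7.2,
    "TA": -7.2,
    "CA": -8.5, "TG": -8.5,
    "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8,
    "GA": -8.2, "TC": -8.2,
    "CG": -10.6,
    "GC": -9.8,
    "GG": -8.0, "CC": -8.0
  },
  "nn_entropy": {
    "AA": -22.2, "TT": -22.2,
    "AT": -20.4,
    "TA": -21.3,
    "CA": -22.7, "TG": -22.7,
    "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0,
    "GA": -22.2, "TC": -22.2,
    "CG": -27.2,
    "GC": -24.4,
    "GG": -19.9, "CC": -19.9
  },
  "init_enthalpy": {"GC": 0.1, "AT": 2.3},
  "init_entropy": {"GC": -2.8, "AT": 4.1},
  "symmetry_entropy": -1.4
}
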