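{
  "comment": "Nearest-neighbor free-energy parameters (delta-G at 37 C, kcal/mol) for the single stem-loop folding model. Stacks are keyed as 'P/Q' where P is the exterior pair and Q the interior pair, each written 5'-base then 3'-base. Only one member of each symmetry-equivalent stack is listed; the loader completes the table via stack[P][Q] = stack[flip(Q)][flip(P)]. Watson-Crick values follow the standard Turner 37 C set; wobble-pair values are the commonly used approximations. Loop initiation penalties are by number of unpaired bases; sizes beyond the table extrapolate with the Jacobson-Stockmayer term 1.75*RT*ln(n/n_max).",
  "stack": {
    "AU/AU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CG/UA": -2.08,
    "CG/AU": -2.11,
    "GC/UA": -2.24,
    "GC/AU": -2.35,
    "CG/GC": -2.36,
    "GC/GC": -3.26,
    "GC/CG": -3.42,
    "AU/GU": -0.55,
    "AU/UG": -1.36,
    "CG/GU": -1.41,
    "CG/UG": -2.11,
    "GC/GU": -1.53,
    "GC/UG": -2.51,
    "UA/GU": -1.27,
    "UA/UG": -1.00,
    "GU/GU": -0.50,
    "UG/UG": -0.50,
    "GU/UG": 0.47,
    "UG/GU": -0.57
  },
  "hairpin_init": {"3": 5.4, "4": 5.6, "5": 5.7, "6": 5.4, "7": 6.0, "8": 5.5, "9": 6.4},
  "bulge_init": {"1": 3.8, "2": 2.8, "3": 3.2, "4": 3.6, "5": 4.0, "6": 4.4},
  "internal_init": {"2": 1.0, "3": 1.4, "4": 1.7, "5": 1.8, "6": 2.0, "7": 2.2, "8": 2.3, "9": 2.4, "10": 2.5},
  "terminal_au": 0.45,
  "rt37": 0.6163
}
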