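"""Nearest-neighbor energy model for the stem-loop folder.

Loads the ΔG°37 parameter table shipped with the package and exposes it as
numpy arrays plus loop-penalty functions.  Pairs are encoded as integers::

    0 AU   1 UA   2 CG   3 GC   4 GU   5 UG

Loop sizes beyond the tabulated range use the Jacobson-Stockmayer
extrapolation ``dG(n) = dG(n_max) + 1.75 * RT * ln(n / n_max)``.
"""

from __future__ import annotations

import json
import math
from functools import lru_cache
from importlib import resources

import numpy as np

PAIR_NAMES = ("AU", "UA", "CG", "GC", "GU", "UG")
PAIR_CODE = {name: i for i, name in enumerate(PAIR_NAMES)}

# nucleotide codes: A=0 C=1 G=2 U/T=3
NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

#: pair code for (base5, base3), -1 if not pairable
PAIR_TABLE = np.full((4, 4), -1, dtype=np.int8)
for _name in PAIR_NAMES:
    PAIR_TABLE[NT_CODE[_name[0]], NT_CODE[_name[1]]] = PAIR_CODE[_name]


def _flip(pair: str) -> str:
    return pair[1] + pair[0]


def _load_params() -> dict:
    with resources.files("srnaforge.data").joinpath("nn_params.json").open() as fh:
        return json.load(fh)


_P = _load_params()

RT37 = float(_P["rt37"])
TERMINAL_AU = float(_P["terminal_au"])

#: STACK[p, q] = ΔG of interior pair q stacked under exterior pair p
STACK = np.full((6, 6), np.nan)
for _key, _val in _P["stack"].items():
    _p, _q = _key.split("/")
    STACK[PAIR_CODE[_p], PAIR_CODE[_q]] = _val
    STACK[PAIR_CODE[_flip(_q)], PAIR_CODE[_flip(_p)]] = _val
assert not np.isnan(STACK).any(), "stack table incomplete after symmetry closure"

_HAIRPIN = {int(k): v for k, v in _P["hairpin_init"].items()}
_BULGE = {int(k): v for k, v in _P["bulge_init"].items()}
_INTERNAL = {int(k): v for k, v in _P["internal_init"].items()}


def _looked_up(table: dict[int, float], n: int) -> float:
    if n in table:
        return table[n]
    n_max = max(table)
    return table[n_max] + 1.75 * RT37 * math.log(n / n_max)


@lru_cache(maxsize=None)
def hairpin_dg(loop_size: int) -> float:
    """Hairpin-loop initiation penalty; loops below 3 nt are sterically forbidden."""
    if loop_size < 3:
        return math.inf
    return _looked_up(_HAIRPIN, loop_size)


@lru_cache(maxsize=None)
def bulge_dg(size: int) -> float:
    if size < 1:
        raise ValueError("bulge size must be >= 1")
    return _looked_up(_BULGE, size)


@lru_cache(maxsize=None)
def internal_dg(size: int) -> float:
    if size < 2:
        raise ValueError("internal loop size must be >= 2")
    return _looked_up(_INTERNAL, size)


def encode(seq: str) -> np.ndarray:
    """Map an RNA/DNA string to integer codes; raises on other characters."""
    try:
        return np.array([NT_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGTU character in sequence: {exc.args[0]!r}") from None


def pair_code(a: int, b: int) -> int:
    return int(PAIR_TABLE[a, b])


def is_au_like(code: int) -> bool:
    """True for pairs subject to the terminal AU/GU penalty."""
    return code != PAIR_CODE["CG"] and code != PAIR_CODE["GC"]
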