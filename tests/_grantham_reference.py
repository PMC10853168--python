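"""Reference Grantham distance table, reconstructed independently.

This is a synthetic stand-in for the printed 1974 distance table: it is
recomputed here from the published formula, property table (c, p, v) and
constants (alpha, beta, gamma, and rho fixed by normalizing the mean
inter-residue distance to 100), using plain-Python scalar arithmetic that
shares no code with the package implementation. Widely attested anchor
values (Leu-Ile = 5; Cys-Trp = 215, the maximum; mean off-diagonal 100)
pin the convention.
"""

import math

# property table typed independently of the package source
_PROPS = {
    "A": (0.00, 8.1, 31.0),
    "C": (2.75, 5.5, 55.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "F": (0.00, 5.2, 132.0),
    "G": (0.74, 9.0, 3.0),
    "H": (0.58, 10.4, 96.0),
    "I": (0.00, 5.2, 111.0),
    "K": (0.33, 11.3, 119.0),
    "L": (0.00, 4.9, 111.0),
    "M": (0.00, 5.7, 105.0),
    "N": (1.33, 11.6, 56.0),
    "P": (0.39, 8.0, 32.5),
    "Q": (0.89, 10.5, 85.0),
    "R": (0.65, 10.5, 124.0),
    "S": (1.42, 9.2, 32.0),
    "T": (0.71, 8.6, 61.0),
    "V": (0.00, 5.9, 84.0),
    "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0),
}

_ALPHA, _BETA, _GAMMA = 1.833, 0.1018, 0.000399


def _raw(a: str, b: str) -> float:
    ca, pa, va = _PROPS[a]
    cb, pb, vb = _PROPS[b]
    return math.sqrt(
        _ALPHA * (ca - cb) ** 2 + _BETA * (pa - pb) ** 2 + _GAMMA * (va - vb) ** 2
    )


def reference_table() -> dict:
    """Integer distance per unordered residue pair, plus rho used."""
    residues = sorted(_PROPS)
    pairs = [
        (a, b) for i, a in enumerate(residues) for b in residues[i + 1 :]
    ]
    mean_raw = sum(_raw(a, b) for a, b in pairs) / len(pairs)
    rho = 100.0 / mean_raw
    table = {}
    for a, b in pairs:
        table[(a, b)] = math.floor(rho * _raw(a, b) + 0.5)
    return table
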