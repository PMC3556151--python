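"""IUPAC degenerate-base tables shared across consensus and design code."""

from __future__ import annotations

BASES = ("A", "C", "G", "T")

CODE_TO_SET: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    # N carries no allele information here: downstream expansion treats it
    # as "no evidence", and 4-allele unions are emitted as N by policy.
    "N": frozenset(),
}

SET_TO_CODE: dict[frozenset[str], str] = {
    s: c for c, s in CODE_TO_SET.items() if c != "N"
}


def expand(symbol: str) -> frozenset[str]:
    """Base set implied by a consensus symbol (N -> empty set)."""
    try:
        return CODE_TO_SET[symbol.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide symbol: {symbol!r}") from None


def code_for(bases) -> str:
    """Single symbol for a base set; empty or 4-base sets collapse to N."""
    s = frozenset(b.upper() for b in bases)
    if not s or len(s) == 4:
        return "N"
    try:
        return SET_TO_CODE[s]
    except KeyError:
        raise ValueError(f"not a nucleotide base set: {sorted(s)}") from None


def is_ambiguous(symbol: str) -> bool:
    """True for anything that is not a plain A/C/G/T."""
    return symbol.upper() not in BASES
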