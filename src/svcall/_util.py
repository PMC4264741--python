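"""Small shared helpers."""

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# Relative read orientation in coordinate order: first character is the
# strand of the leftmost (or lower-chromosome) mate, second of the other.
_STRANDS2ORIENT = {
    ("+", "-"): "FR",
    ("-", "+"): "RF",
    ("+", "+"): "FF",
    ("-", "-"): "RR",
}
_ORIENT2STRANDS = {v: k for k, v in _STRANDS2ORIENT.items()}


def orientation_of(strand1: str, strand2: str) -> str:
    return _STRANDS2ORIENT[(strand1, strand2)]


def strands_of(orientation: str) -> tuple[str, str]:
    return _ORIENT2STRANDS[orientation]
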