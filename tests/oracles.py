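"""Independent brute-force reference for pentapeptide classification.

Deliberately takes a different route from the package: the canonical
rule is evaluated by literal counting, and the relaxed classes are
decided by explicit residue substitution followed by a canonical
re-check, enumerating every allowed substitution.
"""

HYDROPHOBIC = set("FILV")
BASIC = set("KR")
ACIDIC = set("DE")
PHOSPHO = set("STY")


def is_canonical(window: str) -> bool:
    for anchor_pos in (0, 4):
        if window[anchor_pos] != "Q":
            continue
        flanks = [window[i] for i in range(5) if i != anchor_pos]
        h = sum(r in HYDROPHOBIC for r in flanks)
        b = sum(r in BASIC for r in flanks)
        a = sum(r in ACIDIC for r in flanks)
        if h + b + a == 4 and 1 <= h <= 2 and 1 <= b <= 2 and a == 1:
            return True
    return False


def _phospho_variants(window: str):
    """Every single S/T/Y -> acidic substitution."""
    for i, res in enumerate(window):
        if res in PHOSPHO:
            yield window[:i] + "D" + window[i + 1 :]


def _acetyl_variants(window: str):
    """Every terminal K -> Q substitution."""
    for i in (0, 4):
        if window[i] == "K":
            yield window[:i] + "Q" + window[i + 1 :]


def classify(window: str):
    """Reference classification with the canonical>phospho>acetyl>dual
    priority; returns the class name or None."""
    if is_canonical(window):
        return "canonical"
    if any(is_canonical(v) for v in _phospho_variants(window)):
        return "phospho"
    if any(is_canonical(v) for v in _acetyl_variants(window)):
        return "acetyl"
    for v in _acetyl_variants(window):
        if any(is_canonical(w) for w in _phospho_variants(v)):
            return "phospho+acetyl"
    return None
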