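"""KFERQ-like motif scanning and classification.

Chaperone-mediated autophagy (CMA) substrates carry a pentapeptide
targeting signal related to KFERQ.  A window qualifies when a glutamine
(Q) anchors one end and the four flanking residues follow a composition
rule: one or two hydrophobic residues {F, I, L, V}, one or two basic
residues {K, R}, and exactly one acidic residue {D, E}, the four counts
summing to four.  Non-canonical variants are "activated" by
post-translational modification: a phosphorylated S/T/Y can stand in for
the acidic residue (phospho-activated), and an acetylated lysine at a
terminal position can stand in for the Q anchor (acetyl-activated); a
window may require both relaxations at once (phospho+acetyl).

Class priority is total: canonical > phospho > acetyl > phospho+acetyl >
none, so every window receives at most one class.  Asparagine (N) is not
accepted as a Q substitute.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

HYDROPHOBIC = frozenset("FILV")
BASIC = frozenset("KR")
ACIDIC = frozenset("DE")
PHOSPHO_MIMIC = frozenset("STY")  # acidic when phosphorylated
Q_MIMIC_BY_ACETYL = frozenset("K")  # Q-like anchor when acetylated
ANCHOR = frozenset("Q")

#: Exclusive motif classes, in priority order.
CLASS_CANONICAL = "canonical"
CLASS_PHOSPHO = "phospho"
CLASS_ACETYL = "acetyl"
CLASS_PHOSPHO_ACETYL = "phospho+acetyl"
MOTIF_CLASSES = (CLASS_CANONICAL, CLASS_PHOSPHO, CLASS_ACETYL, CLASS_PHOSPHO_ACETYL)

NO_MOTIF = "no motif"


@dataclass(frozen=True)
class MotifHit:
    """A classified pentapeptide window within a protein sequence."""

    protein_id: str
    start: int  # 0-based offset of the window
    window: str
    motif_class: str
    anchor_end: str  # "N" (position 0) or "C" (position 4)
    required_mods: tuple = ()  # ((offset, modification), ...)


@dataclass(frozen=True)
class MotifProfile:
    """Per-protein motif summary: distinct classes and exclusive category."""

    protein_id: str
    class_set: frozenset
    category: str


def _flank_counts(flanks: str) -> tuple[int, int, int, int]:
    """Counts of (hydrophobic, basic, acidic, phospho-mimic) among flanks."""
    h = b = a = m = 0
    for res in flanks:
        if res in HYDROPHOBIC:
            h += 1
        elif res in BASIC:
            b += 1
        elif res in ACIDIC:
            a += 1
        elif res in PHOSPHO_MIMIC:
            m += 1
    return h, b, a, m


def _composition_ok(h: int, b: int, a: int, m: int, *, phospho: bool) -> bool:
    # All four flanks must be classed.  Without relaxation the acidic count
    # is exactly 1; with the phospho relaxation exactly one S/T/Y supplies
    # the acidic residue instead.  In both cases h and b must each be 1-2
    # (h + b = 3 follows from the totals).
    if phospho:
        if a != 0 or m != 1:
            return False
    else:
        if a != 1 or m != 0:
            return False
    if h + b != 3:
        return False
    return 1 <= h <= 2 and 1 <= b <= 2


def classify_pentapeptide(window: str) -> str | None:
    """Classify a 5-residue window; return the motif class or ``None``.

    Raises ``ValueError`` on a window that is not exactly five standard
    residues.  The C-terminal anchor (position 4, as in KFERQ itself) is
    checked before the N-terminal one.
    """
    detail = classify_pentapeptide_detail(window)
    return None if detail is None else detail[0]


def classify_pentapeptide_detail(window: str) -> tuple[str, str, tuple] | None:
    """Like :func:`classify_pentapeptide` but also report the anchor end
    ("N"/"C") and the required modifications ``((offset, kind), ...)``."""
    window = window.upper()
    if len(window) != 5:
        raise ValueError(f"window must have length 5, got {len(window)}")
    for res in window:
        if res not in AMINO_ACIDS:
            raise ValueError(f"nonstandard residue {res!r} in window {window!r}")

    # (anchor position, flanks); C end first so KFERQ reports anchor_end="C".
    ends = ((4, window[:4], "C"), (0, window[1:], "N"))

    for needs_acetyl in (False, True):
        anchor_set = Q_MIMIC_BY_ACETYL if needs_acetyl else ANCHOR
        for needs_phospho in (False, True):
            for pos, flanks, end in ends:
                if window[pos] not in anchor_set:
                    continue
                h, b, a, m = _flank_counts(flanks)
                if not _composition_ok(h, b, a, m, phospho=needs_phospho):
                    continue
                mods = []
                if needs_phospho:
                    off = next(
                        i if pos == 4 else i + 1
                        for i, res in enumerate(flanks)
                        if res in PHOSPHO_MIMIC
                    )
                    mods.append((off, "phosphorylation"))
                if needs_acetyl:
                    mods.append((pos, "acetylation"))
                if needs_acetyl and needs_phospho:
                    cls = CLASS_PHOSPHO_ACETYL
                elif needs_acetyl:
                    cls = CLASS_ACETYL
                elif needs_phospho:
                    cls = CLASS_PHOSPHO
                else:
                    cls = CLASS_CANONICAL
                return cls, end, tuple(mods)
    return None


def scan_sequence(sequence: str, protein_id: str = "") -> list[MotifHit]:
    """Scan every pentapeptide window of ``sequence`` (0-based starts).

    Overlapping hits are allowed.  Windows containing nonstandard
    residues (X, U, ...) are treated as motif-free rather than raising,
    so real UniProt sequences scan cleanly.
    """
    sequence = sequence.upper()
    if len(sequence) < 5:
        raise ValueError("sequence shorter than 5 residues cannot be scanned")
    hits: list[MotifHit] = []
    for start in range(len(sequence) - 4):
        window = sequence[start : start + 5]
        try:
            detail = classify_pentapeptide_detail(window)
        except ValueError:
            continue
        if detail is None:
            continue
        cls, end, mods = detail
        hits.append(
            MotifHit(
                protein_id=protein_id,
                start=start,
                window=window,
                motif_class=cls,
                anchor_end=end,
                required_mods=mods,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Per-protein categorization (exclusive categories for reporting)
# ---------------------------------------------------------------------------

_BASE_CATEGORY = {
    frozenset(): NO_MOTIF,
    frozenset({CLASS_CANONICAL}): "canonical",
    frozenset({CLASS_PHOSPHO}): "phospho",
    frozenset({CLASS_ACETYL}): "acetyl",
    frozenset({CLASS_PHOSPHO, CLASS_ACETYL}): "phospho&acetyl",
    frozenset({CLASS_CANONICAL, CLASS_PHOSPHO}): "canonical&phospho",
    frozenset({CLASS_CANONICAL, CLASS_ACETYL}): "canonical&acetyl",
    frozenset({CLASS_CANONICAL, CLASS_PHOSPHO, CLASS_ACETYL}): "all three",
}


def categorize_protein(
    hits: Sequence[MotifHit],
    protein_id: str | None = None,
    *,
    fold_dual_into_parents: bool = True,
) -> MotifProfile:
    """Collapse a protein's hits into one exclusive category.

    The dual phospho+acetyl class is by default folded into both parent
    classes (a protein whose only motif needs both modifications counts
    as having phospho- and acetyl-activated potential); with
    ``fold_dual_into_parents=False`` it is surfaced in its own combined
    label instead.
    """
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(ids)}")
    if protein_id is None:
        protein_id = next(iter(ids)) if ids else ""

    class_set = frozenset(h.motif_class for h in hits)
    effective = set(class_set)
    if fold_dual_into_parents and CLASS_PHOSPHO_ACETYL in effective:
        effective.discard(CLASS_PHOSPHO_ACETYL)
        effective.update({CLASS_PHOSPHO, CLASS_ACETYL})
    key = frozenset(effective)
    category = _BASE_CATEGORY.get(key)
    if category is None:  # only reachable when the dual class is kept apart
        category = "&".join(sorted(key))
    return MotifProfile(protein_id=protein_id, class_set=class_set, category=category)


def profile_sequences(
    records: Mapping[str, str] | Iterable[tuple[str, str]],
    **categorize_kwargs,
) -> tuple[list[MotifHit], list[MotifProfile]]:
    """Scan and categorize many ``(protein_id, sequence)`` pairs."""
    items = records.items() if isinstance(records, Mapping) else records
    all_hits: list[MotifHit] = []
    profiles: list[MotifProfile] = []
    for protein_id, sequence in items:
        hits = scan_sequence(sequence, protein_id)
        all_hits.extend(hits)
        profiles.append(categorize_protein(hits, protein_id, **categorize_kwargs))
    return all_hits, profiles


# ---------------------------------------------------------------------------
# Breakdown panels (motif content x regulation direction)
# ---------------------------------------------------------------------------

def motif_breakdown(profiles: Sequence[MotifProfile], calls: Sequence) -> dict:
    """Join per-protein motif profiles with regulation calls and summarize.

    Returns a dict with three panels: (i) the percentage of proteins
    carrying at least one motif; (ii) among motif-containing proteins,
    the percentage up- vs downregulated (over up+down); (iii) the
    percentage per exclusive motif category over motif-containing
    proteins.  Percentages are rounded to integers.  Panels that would
    divide by zero are reported as ``None`` rather than 0.
    """
    call_by_id = {c.protein_id: c.call for c in calls}
    joined = [p for p in profiles if p.protein_id in call_by_id]
    if not joined:
        raise ValueError("no proteins shared between profiles and calls")

    n_total = len(joined)
    with_motif = [p for p in joined if p.category != NO_MOTIF]
    n_motif = len(with_motif)

    out: dict = {
        "n_proteins": n_total,
        "n_with_motif": n_motif,
        "pct_with_motif": round(100 * n_motif / n_total),
    }

    if n_motif == 0:
        out["regulation_among_motif"] = None
        out["category_pct"] = None
        return out

    ups = sum(1 for p in with_motif if call_by_id[p.protein_id] == "up")
    downs = sum(1 for p in with_motif if call_by_id[p.protein_id] == "down")
    if ups + downs == 0:
        out["regulation_among_motif"] = None
    else:
        out["regulation_among_motif"] = {
            "n_up": ups,
            "n_down": downs,
            "pct_up": round(100 * ups / (ups + downs)),
            "pct_down": round(100 * downs / (ups + downs)),
        }

    cat_counts = Counter(p.category for p in with_motif)
    out["category_counts"] = dict(sorted(cat_counts.items()))
    out["category_pct"] = {
        cat: round(100 * n / n_motif) for cat, n in sorted(cat_counts.items())
    }
    return out


# ---------------------------------------------------------------------------
# Exhaustive census and closed-form check
# ---------------------------------------------------------------------------

def pentapeptide_census() -> dict[str, int]:
    """Classify all 20**5 = 3,200,000 pentapeptides (vectorized).

    Returns counts per motif class plus ``"none"``.  Useful both as a
    global sanity check of the rule set and to gauge how permissive each
    class is.
    """
    n_aa = len(AMINO_ACIDS)
    idx = np.arange(n_aa, dtype=np.uint8)
    grids = np.meshgrid(*([idx] * 5), indexing="ij")
    win = np.stack([g.ravel() for g in grids], axis=1)  # (N, 5)

    def lut(members: frozenset) -> np.ndarray:
        return np.array([aa in members for aa in AMINO_ACIDS])

    is_h, is_b, is_a = lut(HYDROPHOBIC), lut(BASIC), lut(ACIDIC)
    is_m, is_q, is_k = lut(PHOSPHO_MIMIC), lut(ANCHOR), lut(Q_MIMIC_BY_ACETYL)

    def flank_ok(cols: np.ndarray, phospho: bool) -> np.ndarray:
        h = is_h[cols].sum(axis=1)
        b = is_b[cols].sum(axis=1)
        a = is_a[cols].sum(axis=1)
        m = is_m[cols].sum(axis=1)
        if phospho:
            base = (a == 0) & (m == 1)
        else:
            base = (a == 1) & (m == 0)
        return base & (h + b == 3) & (h >= 1) & (h <= 2)

    flank_c = win[:, :4]  # anchor at position 4
    flank_n = win[:, 1:]  # anchor at position 0
    anchor_c, anchor_n = win[:, 4], win[:, 0]

    def anchored(anchor_lut: np.ndarray, phospho: bool) -> np.ndarray:
        return (anchor_lut[anchor_c] & flank_ok(flank_c, phospho)) | (
            anchor_lut[anchor_n] & flank_ok(flank_n, phospho)
        )

    canonical = anchored(is_q, phospho=False)
    phospho = anchored(is_q, phospho=True) & ~canonical
    acetyl = anchored(is_k, phospho=False) & ~canonical & ~phospho
    dual = anchored(is_k, phospho=True) & ~canonical & ~phospho & ~acetyl

    counts = {
        CLASS_CANONICAL: int(canonical.sum()),
        CLASS_PHOSPHO: int(phospho.sum()),
        CLASS_ACETYL: int(acetyl.sum()),
        CLASS_PHOSPHO_ACETYL: int(dual.sum()),
    }
    counts["none"] = n_aa**5 - sum(counts.values())
    return counts


def canonical_count_closed_form() -> int:
    """Combinatorial count of canonical pentapeptides.

    For each anchor end: the four flanks split as (hydrophobic, basic,
    acidic) = (2,1,1) or (1,2,1).  Position choices times residue
    choices give C(4,2)*4^2*(2*2*2) + C(4,2)*2^2*(2*4*2) per end; the
    two ends are disjoint because a flanking Q is unclassed, so a window
    cannot be canonical from both.
    """
    n_h, n_b, n_a = len(HYDROPHOBIC), len(BASIC), len(ACIDIC)
    per_end = comb(4, 2) * n_h**2 * (2 * n_b * n_a) + comb(4, 2) * n_b**2 * (
        2 * n_h * n_a
    )
    return 2 * per_end


def read_fasta(path) -> list[tuple[str, str]]:
    """Read protein sequences from FASTA as ``(protein_id, sequence)``.

    UniProt-style headers (``sp|P12345|NAME ...``) are parsed down to
    the accession; any other header keeps its first token.
    """
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        parts = ident.split("|")
        if len(parts) >= 3 and parts[0] in ("sp", "tr"):
            ident = parts[1]
        records.append((ident, str(rec.seq)))
    return records


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def hits_to_table(hits: Sequence[MotifHit]):
    """Per-hit table (protein, start, window, class, anchor end, mods)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "protein_id": [h.protein_id for h in hits],
            "start": [h.start for h in hits],
            "window": [h.window for h in hits],
            "motif_class": [h.motif_class for h in hits],
            "anchor_end": [h.anchor_end for h in hits],
            "required_mods": [
                ";".join(f"{off}:{kind}" for off, kind in h.required_mods)
                for h in hits
            ],
        }
    )


def profiles_to_table(profiles: Sequence[MotifProfile]):
    import pandas as pd

    return pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in profiles],
            "classes": [",".join(sorted(p.class_set)) for p in profiles],
            "category": [p.category for p in profiles],
        }
    )


def write_breakdown(breakdown: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(breakdown, fh, indent=2, sort_keys=True)
        fh.write("\n")
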