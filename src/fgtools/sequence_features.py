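"""Motif scanning and residue-class composition profiling for FG-repeat
(low-complexity) nucleoporin sequences.

FG-nucleoporins such as Nup98 carry dozens of phenylalanine–glycine (FG)
dipeptide repeats, a subset of which occur in the extended GLFG context.
"Canonical" GLFG means the exact tetrapeptide; "GLFG-like" motifs follow the
looser XLFX pattern (any residue, Leu, Phe, any residue) — the relaxation is
motivated by naturally occurring variants such as SLFS that behave like GLFG
motifs.  All coordinates are 1-based inclusive in the sequence's own
(author) numbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import SequenceRecord

__all__ = [
    "MotifHit",
    "FGStats",
    "CompositionProfile",
    "DEFAULT_CLASSES",
    "scan_motifs",
    "fg_statistics",
    "composition_profile",
    "hits_to_table",
    "hits_to_bed",
]

#: residue classes used for composition profiles (colour scheme of low-
#: complexity-domain sequence maps)
DEFAULT_CLASSES: dict[str, str] = {
    "hydrophobic": "ILVM",
    "aromatic": "FYW",
    "positive": "KRH",
    "negative": "ED",
    "amide_polar": "QN",
    "hydroxyl_polar": "ST",
    "glycine": "G",
    "proline": "P",
    "alanine": "A",
    "cysteine": "C",
}


@dataclass(frozen=True)
class MotifHit:
    pattern_name: str
    start: int  # 1-based inclusive, in the record's numbering
    end: int    # inclusive
    matched: str


@dataclass(frozen=True)
class FGStats:
    n_phe: int
    n_fg: int
    n_glfg_like: int
    n_glfg_canonical: int


@dataclass
class CompositionProfile:
    class_map: dict[str, str]
    window: int
    densities: pd.DataFrame  # index: residue numbers; columns: class names
    field_names: tuple = field(default=(), repr=False)


def _pattern_to_regex(pattern: str) -> re.Pattern:
    if not pattern:
        raise ValueError("empty motif pattern")
    parts = []
    for ch in pattern.upper():
        if ch == "X":
            parts.append("[A-Z]")
        elif ch.isalpha():
            parts.append(re.escape(ch))
        else:
            raise ValueError(f"illegal pattern character {ch!r}")
    # lookahead so overlapping matches are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def scan_motifs(seq: SequenceRecord, pattern: str, pattern_name: str | None = None) -> list[MotifHit]:
    """All (overlapping) occurrences of *pattern*, sorted by start.

    ``X`` in the pattern matches any residue; other letters match exactly.
    """
    rx = _pattern_to_regex(pattern)
    name = pattern_name or pattern.upper()
    hits = []
    for m in rx.finditer(seq.residues):
        matched = m.group(1)
        start = seq.start_number + m.start()
        hits.append(MotifHit(pattern_name=name, start=start, end=start + len(matched) - 1, matched=matched))
    return hits


def count_overlapping(seq: str, pattern: str) -> int:
    return len(list(_pattern_to_regex(pattern).finditer(seq.upper())))


def fg_statistics(seq: SequenceRecord, like_pattern: str = "XLFX") -> FGStats:
    """Census of F residues, FG dipeptides and (canonical) GLFG-class motifs.

    ``like_pattern`` defines what counts as "GLFG-like" (default XLFX).
    """
    s = seq.residues
    return FGStats(
        n_phe=s.count("F"),
        n_fg=count_overlapping(s, "FG"),
        n_glfg_like=count_overlapping(s, like_pattern),
        n_glfg_canonical=count_overlapping(s, "GLFG"),
    )


def composition_profile(
    seq: SequenceRecord,
    window: int = 1,
    class_map: dict[str, str] | None = None,
) -> CompositionProfile:
    """Sliding-window residue-class fractions along the sequence.

    At each position the window is centred (truncated at the edges) and each
    class's density is its letter count divided by the number of *classified*
    letters in the window, so rows sum to 1 wherever the window contains at
    least one classified residue.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    n = len(seq)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    cmap = class_map or DEFAULT_CLASSES
    letter_class: dict[str, str] = {}
    for cls, letters in cmap.items():
        for letter in letters:
            letter_class[letter] = cls
    half = window // 2
    cols = list(cmap)
    data = np.zeros((n, len(cols)))
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        counts = {c: 0 for c in cols}
        n_classified = 0
        for ch in seq.residues[lo:hi]:
            cls = letter_class.get(ch)
            if cls is not None:
                counts[cls] += 1
                n_classified += 1
        if n_classified:
            data[i] = [counts[c] / n_classified for c in cols]
    index = pd.Index([seq.number_of(i) for i in range(n)], name="position")
    return CompositionProfile(class_map=dict(cmap), window=window, densities=pd.DataFrame(data, index=index, columns=cols))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def hits_to_table(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.pattern_name, h.start, h.end, h.matched) for h in hits],
        columns=["pattern", "start", "end", "match"],
    )


def hits_to_bed(hits: list[MotifHit], seq_id: str) -> pd.DataFrame:
    """BED-style table: 0-based half-open coordinates (conversion happens
    only here, at the writer boundary)."""
    return pd.DataFrame(
        [(seq_id, h.start - 1, h.end, h.pattern_name) for h in hits],
        columns=["chrom", "chromStart", "chromEnd", "name"],
    )
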