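"""Isotype demultiplexing by primer matching and qualified-clone filtering.

Sequencing libraries built with nested isotype-specific primers carry the
second-round primer at a fixed position of one mate, so a read's antibody
class (IgA/IgG/IgM) can be recovered by counting mismatches between each
class primer and the first bases of that mate. Reads whose best primer
still exceeds the mismatch budget, or that tie between two classes, stay
unassigned. Downstream, only clone rows with a well-formed CDR3 (>= 4 aa,
no stop, in frame with the nucleotide junction) are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

#: IUPAC nucleotide codes -> set of matching bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: symbols that mark a stop (or frameshift artefact) in an aa junction
STOP_SYMBOLS = ("*", "_")


@dataclass(frozen=True)
class PrimerSet:
    """Isotype-specific primers compared against a fixed read window.

    Parameters
    ----------
    entries:
        ``(isotype label, primer sequence)`` pairs; primers are uppercase
        IUPAC nucleotide codes.
    max_mismatch:
        a read is assigned only when its best primer has strictly fewer
        mismatches than this.
    window_len:
        number of bases from the start of the read compared against the
        primer (the compared span is ``min(window_len, len(primer))``).
    read_end:
        which mate carries the primer ("read1" or "read2").
    """

    entries: tuple[tuple[str, str], ...]
    max_mismatch: int
    window_len: int = 20
    read_end: str = "read1"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("PrimerSet needs at least one primer")
        for label, seq in self.entries:
            bad = [c for c in seq if c not in IUPAC]
            if bad:
                raise ValueError(f"primer {label}: non-IUPAC symbols {bad}")
        if not 0 < self.max_mismatch < self.window_len:
            raise ValueError("require 0 < max_mismatch < window_len")
        if self.read_end not in ("read1", "read2"):
            raise ValueError("read_end must be 'read1' or 'read2'")

    def span(self, primer: str) -> int:
        return min(self.window_len, len(primer))


#: Second-round PCR isotype primers of the in-house library design
#: (compared to 20 nt from the start of read 1, < 5 mismatches).
IN_HOUSE_PRIMERS = PrimerSet(
    entries=(
        ("IgG", "TAGACAGATGGGGSTGTYGTT"),
        ("IgM", "AAGACATTTGGGAAGGACTG"),
        ("IgA", "GTCAGTGGGTAGATGGTGGG"),
    ),
    max_mismatch=5,
    window_len=20,
    read_end="read1",
)

#: IgM-only primer used for the public multi-primer libraries
#: (compared to 20 nt of read 2, < 6 mismatches).
PUBLIC_IGM_PRIMERS = PrimerSet(
    entries=(("IgM", "CGAGGGGGAAGACATTTGGG"),),
    max_mismatch=6,
    window_len=20,
    read_end="read2",
)

PRIMER_SETS = {"in-house": IN_HOUSE_PRIMERS, "public-igm": PUBLIC_IGM_PRIMERS}


def count_mismatches(window: str, primer: str) -> int:
    """Positional (Hamming) mismatch count, IUPAC-aware on the primer side."""
    return sum(base not in IUPAC[code] for base, code in zip(window, primer))


def classify_isotype(read_prefix: str, primers: PrimerSet = IN_HOUSE_PRIMERS) -> str:
    """Assign a read prefix to the isotype of its best-matching primer.

    Returns the isotype label whose primer has the fewest mismatches over
    the compared window provided that count is below ``max_mismatch``;
    otherwise (including an exact tie between two classes) ``"unassigned"``.
    """
    if len(read_prefix) < primers.window_len:
        logger.warning(
            "read prefix of length %d shorter than window %d: unassigned",
            len(read_prefix), primers.window_len,
        )
        return UNASSIGNED
    read_prefix = read_prefix.upper()
    best_label, best_mm, tied = UNASSIGNED, None, False
    for label, primer in primers.entries:
        mm = count_mismatches(read_prefix[: primers.span(primer)], primer)
        if best_mm is None or mm < best_mm:
            best_label, best_mm, tied = label, mm, False
        elif mm == best_mm:
            tied = True
    if best_mm is None or best_mm >= primers.max_mismatch or tied:
        return UNASSIGNED
    return best_label


def locate_primer(read: str, primer: str, max_mismatch: int) -> int | None:
    """Best-matching start position of ``primer`` in ``read``, or None.

    Scans every offset and returns the leftmost position achieving the
    minimal mismatch count, provided it is below ``max_mismatch``.
    """
    read = read.upper()
    best_pos, best_mm = None, max_mismatch
    for pos in range(len(read) - len(primer) + 1):
        mm = count_mismatches(read[pos : pos + len(primer)], primer)
        if mm < best_mm:
            best_pos, best_mm = pos, mm
    return best_pos


def trim_overhang(read: str, primer_location: int) -> str:
    """Remove the synthetic overhang preceding the primer start."""
    if not 0 <= primer_location <= len(read):
        raise ValueError(f"primer location {primer_location} outside read")
    return read[primer_location:]


def demux_reads(
    reads: Iterable[tuple[str, str]],
    primers: PrimerSet = IN_HOUSE_PRIMERS,
) -> pd.DataFrame:
    """Classify reads into isotypes; returns (read_id, isotype) rows.

    For read-1 libraries the primer sits at the read start and the prefix
    is compared directly. For read-2 libraries the primer is first located
    in the read, the overhang before it trimmed, and the trimmed prefix
    classified; a read in which no primer is found stays unassigned.
    """
    rows = []
    for read_id, seq in reads:
        if primers.read_end == "read2":
            pos = None
            for _, primer in primers.entries:
                pos = locate_primer(seq, primer, primers.max_mismatch)
                if pos is not None:
                    break
            if pos is None:
                rows.append((read_id, UNASSIGNED))
                continue
            seq = trim_overhang(seq, pos)
        rows.append((read_id, classify_isotype(seq, primers)))
    return pd.DataFrame(rows, columns=["read_id", "isotype"])


@dataclass(frozen=True)
class CloneRecord:
    """One qualified rearrangement: gene calls, CDR3, abundance, origin."""

    sample_id: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    count: int
    d_gene: str = ""
    mouse_id: str = ""
    strain: str = ""
    tissue: str = ""
    batch: str = ""
    isotype: str = ""

    def __post_init__(self) -> None:
        if len(self.cdr3_aa) < 4:
            raise ValueError("CDR3 shorter than 4 aa")
        if any(s in self.cdr3_aa for s in STOP_SYMBOLS):
            raise ValueError("CDR3 aa contains a stop symbol")
        if len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            raise ValueError("CDR3 nt/aa lengths out of frame")
        if self.count < 1:
            raise ValueError("count must be >= 1")


def filter_qualified(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep clone rows with a qualified CDR3; count what was dropped and why.

    Qualified means: CDR3 aa present and >= 4 residues, no stop symbol,
    nucleotide junction exactly three times the aa length, positive count.
    Each dropped row is tallied under the first rule it violates. The
    filter is idempotent.
    """
    df = df.copy()
    aa = df["cdr3_aa"].fillna("").astype(str)
    nt = df["cdr3_nt"].fillna("").astype(str)
    count = pd.to_numeric(df["count"], errors="coerce")

    missing = (aa == "") | (nt == "")
    short = ~missing & (aa.str.len() < 4)
    stop = ~missing & ~short & aa.str.contains(r"[\*_]", regex=True)
    frame = ~missing & ~short & ~stop & (nt.str.len() != 3 * aa.str.len())
    badcount = ~missing & ~short & ~stop & ~frame & (count.isna() | (count < 1))

    dropped = {
        "missing_cdr3": int(missing.sum()),
        "short_cdr3": int(short.sum()),
        "stop_codon": int(stop.sum()),
        "out_of_frame": int(frame.sum()),
        "nonpositive_count": int(badcount.sum()),
    }
    keep = ~(missing | short | stop | frame | badcount)
    out = df.loc[keep].copy()
    out["count"] = count[keep].astype(int)
    return out.reset_index(drop=True), dropped


_CRITERIA: dict[str, Callable[[pd.DataFrame], float]] = {
    "clones": lambda df: float(df["count"].sum()),
    "clonotypes": lambda df: float(df["cdr3_aa"].nunique()),
}


def select_technical_duplicate(
    replicates: Sequence[pd.DataFrame],
    criterion: str | Callable[[pd.DataFrame], float] = "clones",
) -> pd.DataFrame:
    """Pick the technical replicate with the larger value of ``criterion``.

    ``criterion`` is ``"clones"`` (total clone count), ``"clonotypes"``
    (unique CDR3 aa), or any callable on a clone table. Exact ties break
    by lexicographic sample_id so the choice is deterministic.
    """
    if len(replicates) == 0:
        raise ValueError("no replicates given")
    if len(replicates) == 1:
        return replicates[0]
    score = _CRITERIA[criterion] if isinstance(criterion, str) else criterion

    def sort_key(df: pd.DataFrame) -> tuple[float, str]:
        sid = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns and len(df) else ""
        return (-score(df), sid)

    return min(replicates, key=sort_key)
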