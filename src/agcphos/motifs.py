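"""Activation-segment location and phospho-site classification.

The activation segment of a Ser/Thr kinase domain runs from the DFG motif to
the APE motif and contains the activation loop (AL) with its regulatory
phospho-site (consensus S/T-x-x-G-T, phosphorylated by PDK1 in most AGC
kinases).  A second regulatory site, the hydrophobic motif (HM, consensus
F-x-x-F/Y-S/T-F/Y), sits on the C-terminal tail.  This module locates both
sites, classifies the residue found there (phosphorylatable Ser/Thr,
phosphomimetic Asp/Glu, or other), and maps the three basic residues that
coordinate the AL phosphate (the RSK2 Arg114 / Arg192 / Lys216 triad) onto
every kinase through alignment columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .seqio import AA20, Alignment, KinaseSeq

#: Residues whose hydroxyl accepts the regulatory phosphate.
PHOSPHORYLATABLE = frozenset("ST")
#: Acidic residues used (by evolution or the lab) to imitate the phosphate.
PHOSPHOMIMETIC = frozenset("DE")
#: Positively charged side chains able to pair with the AL phosphate.
BASIC = frozenset("RKH")

#: Degenerate APE terminator: many AGC kinases deviate from literal Ala-Pro-Glu.
APE_PATTERN_DEFAULT = r"[APSG][PIV]E"

SEGMENT_MIN_LEN = 20
SEGMENT_MAX_LEN = 60


class State(str, Enum):
    PHOSPHORYLATABLE = "phosphorylatable"
    PHOSPHOMIMETIC = "phosphomimetic"
    OTHER = "other"
    ABSENT = "absent"


class SiteKind(str, Enum):
    AL = "AL"
    HM = "HM"


@dataclass(frozen=True)
class ActivationSegment:
    """DFG..APE span, 0-based inclusive indices into the ungapped sequence."""

    dfg_start: int
    ape_end: int

    @property
    def length(self) -> int:
        return self.ape_end - self.dfg_start + 1


@dataclass(frozen=True)
class SiteCall:
    """One located (or absent) regulatory phospho-site."""

    kind: SiteKind
    position: int | None  # 0-based; None when absent
    residue: str | None
    state: State
    context: str = ""  # +/-5-residue window around the site
    truncated: bool = False  # HM head found at the extreme C-terminus only

    def __post_init__(self) -> None:
        if self.state is State.ABSENT and self.position is not None:
            raise ValueError("absent site cannot carry a position")


@dataclass(frozen=True)
class TriadCall:
    """Residue found at one phosphate-coordination triad site.

    Sites are named after the RSK2 reference residues: ``R114_site`` on the
    αC-helix, ``R192_site`` in the catalytic loop, ``K216_site`` just after
    the DFG motif.
    """

    site: str
    mapped_residue: str  # 1-letter AA or '-'
    is_basic: bool

    def __post_init__(self) -> None:
        if self.is_basic != (self.mapped_residue in BASIC):
            raise ValueError("is_basic inconsistent with mapped_residue")


@dataclass(frozen=True)
class KinaseRecord:
    """Per-kinase row: site calls, triad residues, activation segment."""

    id: str
    al_call: SiteCall
    hm_call: SiteCall
    triad: tuple[TriadCall, ...] = ()
    segment: ActivationSegment | None = None


def classify_residue(aa: str) -> State:
    """Classify a one-letter residue: S/T phosphorylatable, D/E phosphomimetic,
    anything else (including X) other."""
    if len(aa) != 1 or (aa not in AA20 and aa != "X"):
        raise ValueError(f"not an amino-acid code: {aa!r}")
    if aa in PHOSPHORYLATABLE:
        return State.PHOSPHORYLATABLE
    if aa in PHOSPHOMIMETIC:
        return State.PHOSPHOMIMETIC
    return State.OTHER


def find_activation_segment(
    seq: KinaseSeq, ape_pattern: str = APE_PATTERN_DEFAULT
) -> ActivationSegment | None:
    """Locate the DFG..APE activation segment.

    Scans DFG occurrences left to right; for each, takes the nearest
    downstream APE-like triplet and accepts the first candidate whose
    inclusive length falls in [20, 60] (the family spans 25 aa in PKAα to
    43 aa in MAST1).  Returns None when no acceptable segment exists.
    """
    s = seq.residues
    ape_re = re.compile(ape_pattern)
    for m_dfg in re.finditer("DFG", s):
        start = m_dfg.start()
        for m_ape in ape_re.finditer(s, start + 3):
            end = m_ape.start() + 2  # index of E
            length = end - start + 1
            if length > SEGMENT_MAX_LEN:
                break
            if length >= SEGMENT_MIN_LEN:
                return ActivationSegment(dfg_start=start, ape_end=end)
            # too short: try the next APE-like triplet downstream
    return None


def _context(s: str, pos: int, radius: int = 5) -> str:
    return s[max(0, pos - radius) : pos + radius + 1]


def locate_al_site(
    seq: KinaseSeq,
    segment: ActivationSegment | None,
    column_hint: int | None = None,
    msa: Alignment | None = None,
) -> SiteCall:
    """Locate and classify the activation-loop phospho-site.

    Primary rule: the rightmost position p inside the segment with
    residue(p) in {S,T}, residue(p+3) == G and residue(p+4) == T — the
    consensus S/T-x-x-G-T, nearest the APE end where the AL site sits.
    Fallback: when the consensus fails (e.g. the site carries a
    non-phosphorylatable residue), classify whatever residue occupies the
    alignment column homologous to the reference site (``column_hint``).
    """
    s = seq.residues
    if segment is not None:
        for p in range(segment.ape_end - 4, segment.dfg_start - 1, -1):
            if p < 0 or p + 4 >= len(s):
                continue
            if s[p] in PHOSPHORYLATABLE and s[p + 3] == "G" and s[p + 4] == "T":
                return SiteCall(
                    kind=SiteKind.AL,
                    position=p,
                    residue=s[p],
                    state=classify_residue(s[p]),
                    context=_context(s, p),
                )
    if column_hint is not None:
        if msa is None:
            raise ValueError("column_hint requires the alignment")
        if not (0 <= column_hint < msa.length):
            raise IndexError(
                f"column_hint {column_hint} outside alignment of length {msa.length}"
            )
        pos = msa.ungapped_pos(seq.id, column_hint)
        if pos is not None:
            return SiteCall(
                kind=SiteKind.AL,
                position=pos,
                residue=s[pos],
                state=classify_residue(s[pos]),
                context=_context(s, pos),
            )
    return SiteCall(kind=SiteKind.AL, position=None, residue=None, state=State.ABSENT)


_HM_RE = re.compile("F..[FY]")


def locate_hm_site(seq: KinaseSeq, tail_window: int = 60) -> SiteCall:
    """Locate and classify the hydrophobic-motif site in the C-terminal tail.

    Scans the last *tail_window* residues for F-x-x-[FY]-z-[FY] and reports z
    (the phospho-position).  A bare F-x-x-[FY] head at the extreme C-terminus
    with no z position is reported as a truncated motif (state ``other``),
    the form seen in PKA.  Rightmost full match wins.
    """
    if tail_window <= 6:
        raise ValueError("tail_window must exceed the motif length (6)")
    s = seq.residues
    offset = max(0, len(s) - tail_window)
    tail = s[offset:]
    best: int | None = None
    truncated_start: int | None = None
    for m in _HM_RE.finditer(tail):
        start = m.start()
        z = start + 4
        if z < len(tail) and z + 1 < len(tail) and tail[z + 1] in "FY":
            best = z
        elif z >= len(tail) - 1:
            truncated_start = start
    if best is not None:
        pos = offset + best
        return SiteCall(
            kind=SiteKind.HM,
            position=pos,
            residue=s[pos],
            state=classify_residue(s[pos]),
            context=_context(s, pos),
        )
    if truncated_start is not None:
        pos = offset + truncated_start
        return SiteCall(
            kind=SiteKind.HM,
            position=pos,
            residue=None,
            state=State.OTHER,
            context=_context(s, pos),
            truncated=True,
        )
    return SiteCall(kind=SiteKind.HM, position=None, residue=None, state=State.ABSENT)


TRIAD_SITE_NAMES = ("R114_site", "R192_site", "K216_site")


def map_reference_positions(
    msa: Alignment,
    ref_id: str,
    ref_positions: list[int],
    site_names: tuple[str, ...] | None = None,
) -> dict[str, tuple[TriadCall, ...]]:
    """Map reference-kinase positions onto every row through alignment columns.

    For each 0-based ungapped position of *ref_id*, the alignment column is
    found and every row's residue in that column is reported (gap allowed);
    ``is_basic`` marks Arg/Lys/His, the side chains able to coordinate the
    AL phosphate.  Row order does not affect the result.
    """
    if ref_id not in msa.ids:
        raise KeyError(f"reference id {ref_id!r} not in alignment")
    names = site_names or TRIAD_SITE_NAMES[: len(ref_positions)]
    if len(names) != len(ref_positions):
        raise ValueError("one site name per reference position required")
    cols = [msa.column_of(ref_id, p) for p in ref_positions]
    out: dict[str, tuple[TriadCall, ...]] = {}
    for rid, row in msa.rows:
        calls = []
        for name, col in zip(names, cols):
            aa = row[col]
            calls.append(
                TriadCall(site=name, mapped_residue=aa, is_basic=aa in BASIC)
            )
        out[rid] = tuple(calls)
    return out


def classify_kinome(
    seqs: list[KinaseSeq],
    msa: Alignment | None = None,
    ref_id: str | None = None,
    ref_positions: list[int] | None = None,
    al_column_hint: int | None = None,
    tail_window: int = 60,
    ape_pattern: str = APE_PATTERN_DEFAULT,
) -> list[KinaseRecord]:
    """Compose segment finding, AL/HM site calls and triad mapping per kinase.

    When *msa*, *ref_id* and *ref_positions* are given, triad residues are
    mapped for every row; when *al_column_hint* is given (an alignment column
    homologous to the reference AL site, e.g. RSK2 Ser227), it backs up the
    AL consensus search.  Deterministic given its inputs.
    """
    triads: dict[str, tuple[TriadCall, ...]] = {}
    if msa is not None and ref_id is not None and ref_positions:
        triads = map_reference_positions(msa, ref_id, ref_positions)
    records: list[KinaseRecord] = []
    for seq in seqs:
        try:
            segment = find_activation_segment(seq, ape_pattern=ape_pattern)
            # the column-hint fallback classifies substituted sites inside an
            # accepted segment; a kinase with no accepted segment has no
            # conserved activation loop and is reported AL-absent
            al = locate_al_site(
                seq,
                segment,
                column_hint=al_column_hint if segment is not None else None,
                msa=msa,
            )
            hm = locate_hm_site(seq, tail_window=tail_window)
        except Exception as exc:  # annotate with the kinase id
            raise type(exc)(f"{seq.id}: {exc}") from exc
        records.append(
            KinaseRecord(
                id=seq.id,
                al_call=al,
                hm_call=hm,
                triad=triads.get(seq.id, ()),
                segment=segment,
            )
        )
    return records
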