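"""Backsplice pseudo-junction construction and circular coordinate algebra.

A circRNA is covalently closed, so a binding site may straddle the point
where the 3' end is backspliced onto the 5' end.  Scanning the sequence as
a linear string misses such sites.  The standard remedy is to build a short
pseudo-sequence — the last ``k`` nucleotides joined in front of the first
``k`` nucleotides (default k = 30) — scan it separately, and map hits that
cross the splice point back onto circular coordinates.

For circRNAs shorter than ``k`` the pseudo-sequence is the sequence doubled
(circ + circ), which preserves every boundary-spanning context without
padding.  In both cases the splice point sits at index ``min(k, L)`` of the
pseudo-sequence and circular position 0 of the circRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import NucleotideSequence

DEFAULT_FLANK = 30


@dataclass(frozen=True)
class BacksplicePseudoSequence:
    """The junction pseudo-sequence: 3'-end flank followed by 5'-end flank."""

    circ_id: str
    residues: str
    flank: int
    circ_length: int

    @property
    def boundary(self) -> int:
        """Index where the 3' flank meets the 5' flank (the splice point)."""
        return min(self.flank, self.circ_length)

    @property
    def origin_offset(self) -> int:
        """Circular position of pseudo-sequence index 0."""
        return self.circ_length - self.boundary


def build_junction(circ: NucleotideSequence, k: int = DEFAULT_FLANK) -> BacksplicePseudoSequence:
    """Build the backsplice pseudo-sequence for a circular RNA.

    The last ``k`` nt are joined in front of the first ``k`` nt so the
    splice point sits at index ``min(k, L)``; sequences shorter than ``k``
    are doubled instead.
    """
    if circ.topology != "circular":
        raise ValueError(f"build_junction requires circular topology, got {circ.topology!r}")
    if k < 1:
        raise ValueError(f"flank k must be >= 1, got {k}")
    s = circ.residues
    if len(s) >= k:
        residues = s[-k:] + s[:k]
    else:
        residues = s + s
    return BacksplicePseudoSequence(
        circ_id=circ.id, residues=residues, flank=k, circ_length=len(s)
    )


def calibrate_position(junction_pos: int, L: int, k: int) -> int:
    """Map a pseudo-sequence position to a circular coordinate in [0, L).

    Pseudo-sequence index 0 corresponds to circular position L - min(k, L);
    positions are calibrated back to the beginning of the original input
    sequence by offsetting and reducing modulo L.
    """
    b = min(k, L)
    if not 0 <= junction_pos < 2 * b:
        raise ValueError(
            f"junction_pos {junction_pos} outside pseudo-sequence [0, {2 * b})"
        )
    return ((L - b) + junction_pos) % L


def spans_boundary(start: int, end: int, L: int, k: int) -> bool:
    """True iff the half-open pseudo-sequence interval crosses the splice point.

    A hit that merely touches the boundary (ends or starts exactly there)
    lies wholly within one flank and duplicates a linear-scan hit.
    """
    b = min(k, L)
    if not (0 <= start < end <= 2 * b):
        raise ValueError(f"invalid pseudo-sequence interval [{start}, {end}) for 2b={2 * b}")
    return start < b < end
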