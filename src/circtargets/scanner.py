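"""Seed-anchored miRNA binding-site prediction on circRNAs.

This module authors the site-prediction step of the pipeline: a local
alignment between the reversed miRNA (3'->5') and the target (5'->3'),
scored by complementarity — Watson–Crick pairs reward +5, G:U wobbles +1,
mismatches -3, affine gaps -9/-4 — with substitution scores at the miRNA
seed (positions 2–8 from the 5' end) multiplied by ``seed_scale`` (4.0).
Maximal-scoring non-overlapping sites above ``score_threshold`` (140) are
selected greedily; each is then filtered by a per-column duplex-energy
proxy and, in strict mode, by the requirement of contiguous Watson–Crick
pairing (no wobbles, no gaps) across the whole seed window.

``scan_circ`` applies the scanner to the circRNA body and to the
backsplice pseudo-junction, keeps only boundary-spanning junction hits,
calibrates them onto circular coordinates, and merges the two scans into
per-miRNA site lists and binding-site counts (nbs).

The matrix fill is numba-jitted; everything downstream (traceback, site
selection, filtering) is plain Python.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .backsplice import build_junction, calibrate_position, spans_boundary
from .io_formats import NucleotideSequence

_NEG = -1.0e18
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_BASES = "ACGU"
# (mirna base, target base) -> pair class: 2 = Watson-Crick, 1 = G:U wobble
_WC_PAIRS = {(0, 3), (3, 0), (2, 1), (1, 2)}
_GU_PAIRS = {(2, 3), (3, 2)}


@dataclass(frozen=True)
class ScannerParams:
    """Scoring and filtering parameters for the site scanner.

    Defaults mirror the documented defaults of the classic miRNA scanner
    this module reimplements: alignment score cutoff 140, duplex-energy
    cutoff 1.0 kcal/mol (sites must be <=), seed window at miRNA positions
    2–8 with substitution scores scaled by 4.  ``strict`` demands perfect
    contiguous Watson–Crick seed pairing.
    """

    score_threshold: float = 140.0
    energy_threshold: float = 1.0
    strict: bool = True
    match_wc: float = 5.0
    match_gu: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_start: int = 2  # 1-based miRNA position, inclusive
    seed_end: int = 8  # inclusive
    seed_scale: float = 4.0
    # per-column duplex-energy proxy, kcal/mol
    energy_gc: float = -3.0
    energy_au: float = -2.0
    energy_gu: float = -1.0
    energy_other: float = 1.0

    def __post_init__(self) -> None:
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be > 0")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if not 1 <= self.seed_start <= self.seed_end:
            raise ValueError("seed window must satisfy 1 <= seed_start <= seed_end")
        if self.seed_scale <= 0:
            raise ValueError("seed_scale must be > 0")


@dataclass(frozen=True)
class RawSite:
    """One predicted site in target-local coordinates (0-based half-open)."""

    start: int
    end: int
    mir_start: int  # 0-based, 5'->3' miRNA coordinates, half-open
    mir_end: int
    score: float
    energy: float
    alignment: tuple[str, str, str]
    seed_strict: bool


@dataclass(frozen=True)
class BindingSite:
    """One predicted miRNA site on a circRNA, in circular coordinates.

    ``start`` lies in [0, L); ``end`` = start + site length and exceeds L
    exactly when the site wraps across the backsplice point.
    """

    mirna_id: str
    circ_id: str
    start: int
    end: int
    score: float
    energy: float
    spans_junction: bool
    alignment: tuple[str, str, str]


@dataclass(frozen=True)
class MiRNASiteSummary:
    """Per-miRNA binding-site count (nbs) and best score/energy."""

    mirna_id: str
    nbs: int
    best_score: float
    best_energy: float


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


def _base_score_matrix(params: ScannerParams) -> np.ndarray:
    m = np.full((4, 4), params.mismatch)
    for a, b in _WC_PAIRS:
        m[a, b] = params.match_wc
    for a, b in _GU_PAIRS:
        m[a, b] = params.match_gu
    return m


def _seed_rows(m: int, params: ScannerParams) -> np.ndarray:
    """Boolean mask over reversed-miRNA row indices lying in the seed window."""
    # row i holds mirna_rev[i] = mirna[m-1-i], i.e. 1-based 5' position m - i
    pos = m - np.arange(m)
    return (pos >= params.seed_start) & (pos <= params.seed_end)


@njit(cache=True)
def _fill(S, gap_open, gap_extend, banned):  # pragma: no cover - jitted
    m, n = S.shape
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), _NEG)
    F = np.full((m + 1, n + 1), _NEG)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if banned[j - 1]:
                continue  # H stays 0, E/F stay -inf: no path uses this column
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


def _traceback(H, E, F, S, params: ScannerParams, i: int, j: int):
    """Recover the alignment ending at H[i, j].

    Returns a list of columns in target 5'->3' order; each column is
    (kind, mir_row, tgt_pos) with kind in {"pair", "mgap", "tgap"}:
    ``mgap`` aligns a miRNA residue to a gap, ``tgap`` a target residue to
    a gap.  Precedence diagonal > tgap > mgap; within a gap state, closing
    beats extending (shortest gaps win).  All comparisons are exact: every
    stored cell equals one of its candidate expressions bit-for-bit.
    """
    cols = []
    state = "H"
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0.0:
                break
            if h == H[i - 1, j - 1] + S[i - 1, j - 1]:
                cols.append(("pair", i - 1, j - 1))
                i, j = i - 1, j - 1
            elif h == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols.append(("tgap", -1, j - 1))
            if E[i, j] == H[i, j - 1] + params.gap_open:
                state = "H"
            j -= 1
        else:  # F
            cols.append(("mgap", i - 1, -1))
            if F[i, j] == H[i - 1, j] + params.gap_open:
                state = "H"
            i -= 1
    cols.reverse()
    return cols


def _alignment_strings(cols, mir_rev: str, target: str) -> tuple[str, str, str]:
    mir_line = []
    pair_line = []
    tgt_line = []
    for kind, mi, tj in cols:
        if kind == "pair":
            a, b = mir_rev[mi], target[tj]
            mir_line.append(a)
            tgt_line.append(b)
            key = (_CODE[a], _CODE[b])
            pair_line.append("|" if key in _WC_PAIRS else ":" if key in _GU_PAIRS else " ")
        elif kind == "mgap":
            mir_line.append(mir_rev[mi])
            tgt_line.append("-")
            pair_line.append(" ")
        else:
            mir_line.append("-")
            tgt_line.append(target[tj])
            pair_line.append(" ")
    return "".join(mir_line), "".join(pair_line), "".join(tgt_line)


def duplex_energy(alignment: tuple[str, str, str], params: ScannerParams | None = None) -> float:
    """Per-column duplex-stability proxy in kcal/mol (lower = more stable).

    G:C pairs contribute -3.0, A:U -2.0, G:U wobbles -1.0, and any
    mismatched or gapped column +1.0 (defaults; see
    :class:`ScannerParams`).  This is a monotone stability score, not a
    nearest-neighbor thermodynamic fold.
    """
    params = params or ScannerParams()
    mir_line, pair_line, tgt_line = alignment
    if not (len(mir_line) == len(pair_line) == len(tgt_line)):
        raise ValueError("alignment lines must have equal length")
    total = 0.0
    for a, b in zip(mir_line, tgt_line):
        if a == "-" or b == "-":
            total += params.energy_other
        else:
            pair = {a, b}
            if pair == {"G", "C"}:
                total += params.energy_gc
            elif pair == {"A", "U"}:
                total += params.energy_au
            elif pair == {"G", "U"}:
                total += params.energy_gu
            else:
                total += params.energy_other
    return total


def _seed_is_strict(cols, m: int, params: ScannerParams, mir_rev_codes, tgt_codes) -> bool:
    """Contiguous Watson–Crick pairing across the full seed window?"""
    want = set(range(params.seed_start, params.seed_end + 1))
    idxs = []
    for idx, (kind, mi, tj) in enumerate(cols):
        if kind != "pair":
            continue
        pos = m - mi  # 1-based 5' miRNA position of row mi
        if pos in want:
            if (int(mir_rev_codes[mi]), int(tgt_codes[tj])) not in _WC_PAIRS:
                return False
            idxs.append(idx)
    if len(idxs) != len(want):
        return False
    return max(idxs) - min(idxs) == len(want) - 1


def scan_pair(
    mirna: NucleotideSequence,
    target: str,
    params: ScannerParams | None = None,
) -> list[RawSite]:
    """Predict binding sites of one miRNA on a linear target string.

    Greedily extracts maximal-scoring non-overlapping local alignments
    with score >= ``score_threshold`` (ties broken by smaller target
    start), then filters the retained sites by duplex energy and, in
    strict mode, by perfect seed pairing.  Sites are returned sorted by
    target start, in target-local 0-based half-open coordinates.
    """
    params = params or ScannerParams()
    m = len(mirna.residues)
    if m < 10:
        raise ValueError(f"miRNA {mirna.id!r} shorter than 10 nt")
    if m < params.seed_end:
        raise ValueError(
            f"miRNA {mirna.id!r} ({m} nt) shorter than seed window end {params.seed_end}"
        )
    n = len(target)
    if n == 0:
        return []
    mir_rev = mirna.residues[::-1]
    mir_codes = _encode(mir_rev)
    tgt_codes = _encode(target)
    base = _base_score_matrix(params)
    weights = np.where(_seed_rows(m, params), params.seed_scale, 1.0)
    S = base[mir_codes[:, None], tgt_codes[None, :]] * weights[:, None]
    banned = np.zeros(n, dtype=np.bool_)

    retained: list[RawSite] = []
    while True:
        H, E, F = _fill(S, params.gap_open, params.gap_extend, banned)
        best = H.max()
        if best < params.score_threshold:
            break
        cand_cells = np.argwhere(H == best)
        best_site = None
        for i, j in cand_cells:
            cols = _traceback(H, E, F, S, params, int(i), int(j))
            tpos = [tj for kind, _, tj in cols if tj >= 0]
            mpos = [mi for kind, mi, _ in cols if mi >= 0]
            ts, te = min(tpos), max(tpos) + 1
            key = (ts, te, min(mpos), max(mpos) + 1)
            if best_site is None or key < best_site[0]:
                best_site = (key, cols)
        (ts, te, ms_rev, me_rev), cols = best_site
        aln = _alignment_strings(cols, mir_rev, target)
        energy = duplex_energy(aln, params)
        strict_ok = _seed_is_strict(cols, m, params, mir_codes, tgt_codes)
        # mir_rev rows [ms_rev, me_rev) -> 5'->3' miRNA coords [m-me_rev, m-ms_rev)
        retained.append(
            RawSite(
                start=ts,
                end=te,
                mir_start=m - me_rev,
                mir_end=m - ms_rev,
                score=float(best),
                energy=energy,
                alignment=aln,
                seed_strict=strict_ok,
            )
        )
        banned[ts:te] = True

    sites = [
        s
        for s in retained
        if s.energy <= params.energy_threshold and (not params.strict or s.seed_strict)
    ]
    sites.sort(key=lambda s: s.start)
    return sites


def _circ_positions(start: int, end: int, L: int) -> frozenset[int]:
    return frozenset(p % L for p in range(start, end))


def scan_circ(
    circ: NucleotideSequence,
    mirnas: Sequence[NucleotideSequence],
    params: ScannerParams | None = None,
    k: int = 30,
) -> tuple[list[BindingSite], list[MiRNASiteSummary]]:
    """Scan a circRNA (body + backsplice junction) against a miRNA panel.

    The linear body is scanned directly; the backsplice pseudo-junction is
    scanned separately and only boundary-spanning hits are kept and
    calibrated back to circular coordinates (non-spanning junction hits
    duplicate body hits).  Same-miRNA sites overlapping on the circle are
    resolved greedily by descending score, ties by smaller start.  Returns
    the merged site list and one per-miRNA summary (nbs, best score,
    best energy) for every miRNA with at least one site.
    """
    params = params or ScannerParams()
    if not mirnas:
        raise ValueError("scan_circ requires a non-empty miRNA list")
    if circ.topology != "circular":
        raise ValueError(f"scan_circ requires a circular sequence, got {circ.topology!r}")
    L = circ.length
    junction = build_junction(circ, k)

    sites: list[BindingSite] = []
    for mir in mirnas:
        candidates: list[BindingSite] = []
        for raw in scan_pair(mir, circ.residues, params):
            candidates.append(
                BindingSite(
                    mirna_id=mir.id,
                    circ_id=circ.id,
                    start=raw.start,
                    end=raw.end,
                    score=raw.score,
                    energy=raw.energy,
                    spans_junction=False,
                    alignment=raw.alignment,
                )
            )
        for raw in scan_pair(mir, junction.residues, params):
            if not spans_boundary(raw.start, raw.end, L, k):
                continue
            start = calibrate_position(raw.start, L, k)
            candidates.append(
                BindingSite(
                    mirna_id=mir.id,
                    circ_id=circ.id,
                    start=start,
                    end=start + (raw.end - raw.start),
                    score=raw.score,
                    energy=raw.energy,
                    spans_junction=True,
                    alignment=raw.alignment,
                )
            )
        # drop exact duplicates, then resolve circular overlaps greedily
        seen: set[tuple[int, int]] = set()
        unique = []
        for site in candidates:
            key = (site.start, site.end)
            if key in seen:
                continue
            seen.add(key)
            unique.append(site)
        unique.sort(key=lambda s: (-s.score, s.start, s.end))
        accepted: list[BindingSite] = []
        covered: set[int] = set()
        for site in unique:
            pos = _circ_positions(site.start, site.end, L)
            if pos & covered:
                continue
            covered |= pos
            accepted.append(site)
        sites.extend(accepted)

    sites.sort(key=lambda s: (s.mirna_id, s.start, s.end))
    summaries = []
    by_mir: dict[str, list[BindingSite]] = {}
    for s in sites:
        by_mir.setdefault(s.mirna_id, []).append(s)
    for mirna_id in sorted(by_mir):
        group = by_mir[mirna_id]
        summaries.append(
            MiRNASiteSummary(
                mirna_id=mirna_id,
                nbs=len(group),
                best_score=max(s.score for s in group),
                best_energy=min(s.energy for s in group),
            )
        )
    return sites, summaries


# ---------------------------------------------------------------------------
# Optional pass-through backend for an installed external scanner executable.


def parse_external_scanner_output(text: str) -> list[dict]:
    """Parse the per-hit summary lines of the classic scanner's output.

    Hit lines start with a single ``>`` (aggregate lines use ``>>``) and
    carry tab-separated fields: miRNA id, target id, score, energy, miRNA
    range, target range (each a space-separated 1-based inclusive pair),
    alignment length, identity, similarity.  Coordinates are converted to
    0-based half-open.
    """
    hits = []
    for line in text.splitlines():
        if not line.startswith(">") or line.startswith(">>"):
            continue
        fields = line.lstrip(">").split("\t")
        if len(fields) < 6:
            continue
        tgt_start, tgt_end = (int(x) for x in fields[5].split()[:2])
        hits.append(
            {
                "mirna_id": fields[0].strip(),
                "target_id": fields[1].strip(),
                "score": float(fields[2]),
                "energy": float(fields[3]),
                "start": tgt_start - 1,
                "end": tgt_end,
            }
        )
    return hits


def run_external_scanner(
    mirna_fasta: str,
    target_fasta: str,
    executable: str = "miranda",
    *,
    score_threshold: float = 140.0,
    energy_threshold: float = 1.0,
    strict: bool = True,
) -> list[dict]:
    """Invoke an installed external scanner binary and parse its hits.

    Provided for users who require numeric parity with the classic tool;
    the built-in scanner is the default backend and the tested one.
    """
    cmd = [
        executable,
        mirna_fasta,
        target_fasta,
        "-sc",
        str(score_threshold),
        "-en",
        str(energy_threshold),
    ]
    if strict:
        cmd.append("-strict")
    try:
        proc = subprocess.run(cmd, capture_output=True, text=True, check=True)
    except FileNotFoundError as exc:
        raise RuntimeError(
            f"external scanner executable {executable!r} not found on PATH"
        ) from exc
    return parse_external_scanner_output(proc.stdout)
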