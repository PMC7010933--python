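"""Degenerate pentamer-repeat scanner for heat shock elements (HSEs).

An HSE is a run of ``k`` (3 <= k <= 8) alternating pentamer subunits,
each matching 5'-NGAAN-3' or 5'-NTTCN-3' (positions 1 and 5 are
unconstrained), with at most one mismatched nucleotide in the whole run.
The G at position 2 of NGAAN and the C at position 4 of NTTCN are the
*key* nucleotides.  Admission rules:

1. at least three subunits, orientations strictly alternating;
2. at most one mismatch in total across the run;
3. when the run has exactly three subunits, a key-position mismatch is
   only allowed in the middle subunit;
4. when the run has more than three subunits, key-position mismatches
   are allowed in any subunit.

Classification: *typical* (no mismatch), *gapped* (the single mismatch
is at a key position), *varied* (the single mismatch is at a non-key
constrained position).

Because the motif family is closed under reverse complement (the
reverse complement of nGAAn is nTTCn) a promoter only needs to be
scanned on its coding strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

Orientation = Literal["GAA", "TTC"]

#: constrained bases at 1-based pentamer positions 2..4, per orientation
_CORE = {"GAA": "GAA", "TTC": "TTC"}
#: 1-based key position within the pentamer, per orientation
KEY_POSITION = {"GAA": 2, "TTC": 4}

_FLIP = {"GAA": "TTC", "TTC": "GAA"}


@dataclass(frozen=True)
class Mismatch:
    """A single deviation from the consensus pentamer."""

    position_in_subunit: int  # 1-based, always in {2, 3, 4}
    observed_base: str
    is_key: bool


@dataclass(frozen=True)
class SubunitMatch:
    orientation: Orientation
    offset: int
    mismatches: tuple[Mismatch, ...]


@dataclass(frozen=True)
class HSEMismatch:
    """Mismatch descriptor of a full HSE (subunit_index is 1-based)."""

    subunit_index: int
    position_in_subunit: int
    observed_base: str
    is_key: bool


@dataclass(frozen=True)
class HSEMatch:
    gene_id: Optional[str]
    start_offset: int
    subunit_count: int
    first_orientation: Orientation
    hse_class: str  # typical | gapped | varied
    mismatch: Optional[HSEMismatch]
    distance_to_atg: int
    sequence: str

    @property
    def end_offset(self) -> int:
        return self.start_offset + 5 * self.subunit_count


def match_subunit(pentamer: str, orientation: Orientation) -> Optional[SubunitMatch]:
    """Compare a 5-mer against the nGAAn or nTTCn consensus.

    Returns a :class:`SubunitMatch` carrying the (at most one) mismatch,
    or ``None`` when two or more of the constrained positions deviate.
    Non-ACGT characters at constrained positions count as mismatches;
    the flanking N positions match anything.
    """
    if len(pentamer) != 5:
        raise ValueError(f"subunit must be 5 bp, got {len(pentamer)}")
    core = _CORE[orientation]
    key_pos = KEY_POSITION[orientation]
    mismatches = []
    for i, expected in zip((2, 3, 4), core):
        observed = pentamer[i - 1]
        if observed != expected:
            mismatches.append(Mismatch(i, observed, i == key_pos))
            if len(mismatches) > 1:
                return None
    return SubunitMatch(orientation, 0, tuple(mismatches))


def classify(mismatches: Sequence[Mismatch]) -> str:
    """Class of an admitted run from its mismatch list (length 0 or 1)."""
    if len(mismatches) > 1:
        raise ValueError("an admitted HSE carries at most one mismatch")
    if not mismatches:
        return "typical"
    return "gapped" if mismatches[0].is_key else "varied"


def _slot_status(sequence, phase, first_orientation, n_slots):
    """Per-slot match status for one alternation frame.

    Returns a list where entry ``i`` is ``None`` (>= 2 mismatches, run
    breaker) or a tuple ``(n_mismatch, Mismatch-or-None, orientation)``.
    """
    out = []
    orient = first_orientation
    for i in range(n_slots):
        s = phase + 5 * i
        sub = match_subunit(sequence[s : s + 5], orient)
        if sub is None:
            out.append(None)
        else:
            mm = sub.mismatches[0] if sub.mismatches else None
            out.append((len(sub.mismatches), mm, orient))
        orient = _FLIP[orient]
    return out


def _admissible(status, lo, hi) -> Optional[list[Mismatch]]:
    """Mismatch list if the slot window [lo, hi) is an admissible run."""
    k = hi - lo
    if k < 3:
        return None
    mms = []
    for i in range(lo, hi):
        st = status[i]
        if st is None:
            return None
        if st[0]:
            mms.append((i - lo, st[1]))
    if len(mms) > 1:
        return None
    if k == 3 and mms and mms[0][1].is_key and mms[0][0] != 1:
        return None  # rule 4: terminal key mismatch forbidden at k == 3
    return mms


def _emit(sequence, gene_id, phase, first_orientation, lo, hi, mms,
          max_subunits) -> HSEMatch:
    if hi - lo > max_subunits:  # cap long runs, anchored at the 5' end
        hi = lo + max_subunits
        mms = [m for m in mms if m[0] < max_subunits]
    start = phase + 5 * lo
    k = hi - lo
    mismatch = None
    if mms:
        idx, mm = mms[0]
        mismatch = HSEMismatch(idx + 1, mm.position_in_subunit,
                               mm.observed_base, mm.is_key)
    orient = first_orientation if lo % 2 == 0 else _FLIP[first_orientation]
    seq = sequence[start : start + 5 * k]
    return HSEMatch(
        gene_id=gene_id,
        start_offset=start,
        subunit_count=k,
        first_orientation=orient,
        hse_class=classify([mms[0][1]] if mms else []),
        mismatch=mismatch,
        distance_to_atg=len(sequence) - (start + 5 * k),
        sequence=seq,
    )


def scan_sequence(
    sequence: str,
    gene_id: Optional[str] = None,
    min_subunits: int = 3,
    max_subunits: int = 8,
    maximality: str = "longest-first",
) -> list[HSEMatch]:
    """Find all HSEs on the given (coding) strand of a promoter.

    With ``maximality="longest-first"`` (default) every *maximal*
    admissible run is reported once per alternation frame: a run is not
    reported if an admissible run in the same frame properly contains
    it.  Runs longer than ``max_subunits`` are capped at ``max_subunits``
    subunits anchored at the run's 5' end.  Overlapping HSEs in
    different frames are all reported.  ``maximality="exact-only"``
    instead reports every admissible window.
    """
    if maximality not in ("longest-first", "exact-only"):
        raise ValueError(f"unknown maximality policy: {maximality}")
    sequence = sequence.upper()
    n = len(sequence)
    matches: list[HSEMatch] = []
    for phase in range(5):
        n_slots = (n - phase) // 5
        if n_slots < 3:
            continue
        for first in ("GAA", "TTC"):
            status = _slot_status(sequence, phase, first, n_slots)
            if maximality == "exact-only":
                for lo in range(n_slots):
                    for hi in range(lo + min_subunits,
                                    min(lo + max_subunits, n_slots) + 1):
                        mms = _admissible(status, lo, hi)
                        if mms is not None:
                            matches.append(_emit(sequence, gene_id, phase,
                                                 first, lo, hi, mms,
                                                 max_subunits))
                        elif status[hi - 1] is None:
                            break
                continue
            # longest-first: walk maximal <=1-mismatch intervals inside
            # each break-free stretch of slots.
            i = 0
            while i < n_slots:
                if status[i] is None:
                    i += 1
                    continue
                j = i
                while j < n_slots and status[j] is not None:
                    j += 1
                mm_slots = [t for t in range(i, j) if status[t][0]]
                # maximal <=1-mismatch intervals within the stretch
                intervals = []
                if len(mm_slots) <= 1:
                    intervals.append((i, j))
                else:
                    intervals.append((i, mm_slots[1]))
                    for a in range(1, len(mm_slots) - 1):
                        intervals.append((mm_slots[a - 1] + 1,
                                          mm_slots[a + 1]))
                    intervals.append((mm_slots[-2] + 1, j))
                for lo, hi in intervals:
                    mms = _admissible(status, lo, hi)
                    if mms is None and hi - lo == 3:
                        continue  # 3-subunit run vetoed by rule 4
                    if mms is None:
                        continue
                    if hi - lo >= min_subunits:
                        matches.append(_emit(sequence, gene_id, phase,
                                             first, lo, hi, mms,
                                             max_subunits))
                i = j
    matches.sort(key=lambda m: (m.start_offset, m.subunit_count,
                                m.first_orientation))
    return matches


def brute_force_oracle(
    sequence: str,
    gene_id: Optional[str] = None,
    min_subunits: int = 3,
    max_subunits: int = 8,
) -> list[HSEMatch]:
    """Reference scanner by exhaustive window enumeration (test scale).

    Every window of 5*k bp, at every offset and both starting
    orientations, is checked against the admission rules by direct
    string comparison; the longest-first maximality policy is then
    applied by explicit pairwise containment.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n > 100_000:
        raise ValueError("oracle is for test-scale sequences")

    def window_mismatches(start, first, k):
        mms = []
        orient = first
        for si in range(k):
            for pos, expected in zip((2, 3, 4), _CORE[orient]):
                obs = sequence[start + 5 * si + pos - 1]
                if obs != expected:
                    mms.append((si, Mismatch(pos, obs,
                                             pos == KEY_POSITION[orient])))
            orient = _FLIP[orient]
        return mms

    admissible = []  # (phase, first-at-phase-slot-0, lo_slot, hi_slot, mms)
    for start in range(n - 14):
        for first in ("GAA", "TTC"):
            k = 3
            while start + 5 * k <= n:
                mms = window_mismatches(start, first, k)
                if len(mms) > 1:
                    break
                ok = True
                if k == 3 and mms and mms[0][1].is_key and mms[0][0] != 1:
                    ok = False
                if ok:
                    phase = start % 5
                    lo = (start - phase) // 5
                    f0 = first if lo % 2 == 0 else _FLIP[first]
                    admissible.append((phase, f0, lo, lo + k, mms))
                k += 1

    maximal = []
    for w in admissible:
        phase, f0, lo, hi, mms = w
        contained = any(
            w2 is not w
            and w2[0] == phase and w2[1] == f0
            and w2[2] <= lo and hi <= w2[3]
            and (w2[3] - w2[2]) > (hi - lo)
            for w2 in admissible
        )
        if not contained:
            maximal.append(w)

    out = []
    seen = set()
    for phase, f0, lo, hi, mms in maximal:
        m = _emit(sequence, gene_id, phase, f0, lo, hi, mms, max_subunits)
        key = (m.start_offset, m.subunit_count, m.first_orientation)
        if key not in seen and m.subunit_count >= min_subunits:
            seen.add(key)
            out.append(m)
    out.sort(key=lambda m: (m.start_offset, m.subunit_count,
                            m.first_orientation))
    return out


def scan_promoters(promoters, **kwargs) -> list[HSEMatch]:
    """Scan a collection of :class:`~hsescan.genome_io.Promoter` objects."""
    matches = []
    for p in promoters:
        matches.extend(scan_sequence(p.sequence, gene_id=p.gene_id, **kwargs))
    return matches


def matches_to_frame(matches: Iterable[HSEMatch]) -> pd.DataFrame:
    """Tabulate matches (one row per HSE) for TSV export."""
    rows = []
    for m in matches:
        rows.append(
            {
                "gene_id": m.gene_id,
                "hse_class": m.hse_class,
                "subunit_count": m.subunit_count,
                "start_offset": m.start_offset,
                "distance_to_atg": m.distance_to_atg,
                "first_orientation": m.first_orientation,
                "mismatch_subunit": m.mismatch.subunit_index if m.mismatch else pd.NA,
                "mismatch_position": m.mismatch.position_in_subunit if m.mismatch else pd.NA,
                "mismatch_base": m.mismatch.observed_base if m.mismatch else pd.NA,
                "mismatch_is_key": m.mismatch.is_key if m.mismatch else pd.NA,
                "sequence": m.sequence,
            }
        )
    cols = ["gene_id", "hse_class", "subunit_count", "start_offset",
            "distance_to_atg", "first_orientation", "mismatch_subunit",
            "mismatch_position", "mismatch_base", "mismatch_is_key",
            "sequence"]
    return pd.DataFrame(rows, columns=cols)


def write_matches_tsv(matches: Iterable[HSEMatch], path) -> None:
    matches_to_frame(matches).to_csv(path, sep="\t", index=False)


def read_matches_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
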