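"""Primer-pair feasibility screening for SSR loci.

A lightweight, fully deterministic stand-in for an interactive primer-design
tool: it scans 18–27 nt windows in the flanks of a locus, applies Wallace-rule
melting temperatures and composition constraints, and picks one pair whose
amplicon falls in one of three multiplex-friendly size bins (100–150,
200–300, 350–450 bp).  Forward primers carry a 19-nt universal genotyping
tail (CACGACGTTGTAAAACGAC) used with a dye-labelled third primer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .io_formats import ContigSet
from .ssr_mining import SSRLocus

TAIL = "CACGACGTTGTAAAACGAC"
SIZE_BINS: tuple[tuple[int, int], ...] = ((100, 150), (200, 300), (350, 450))
PRIMER_LEN_RANGE = (18, 27)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(word: str) -> str:
    return word.translate(_COMPLEMENT)[::-1]


def melting_temp(word: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees C."""
    if len(word) < 2:
        raise ValueError("word must have length >= 2")
    counts = Counter(word)
    bad = set(counts) - set("ACGT")
    if bad:
        raise ValueError(f"illegal character(s) {sorted(bad)}")
    at = counts["A"] + counts["T"]
    gc = counts["G"] + counts["C"]
    return 2.0 * at + 4.0 * gc


def gc_fraction(word: str) -> float:
    return (word.count("G") + word.count("C")) / len(word)


def _max_mono_run(word: str) -> int:
    best = run = 1
    for a, b in zip(word, word[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


@dataclass(frozen=True)
class PrimerConstraints:
    gc_min: float = 0.40
    gc_max: float = 0.60
    tm_min: float = 50.0
    tm_max: float = 65.0
    max_tm_diff: float = 5.0
    max_mono_run: int = 3  # runs of 4+ identical bases rejected
    min_flank: int = 30


@dataclass(frozen=True)
class PrimerPair:
    """A feasible primer pair; both cores 5'→3' on their own strands."""

    forward_core: str
    reverse_core: str
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    amplicon_length: int
    size_bin: tuple[int, int]
    forward_start: int  # contig coordinate, 0-based
    reverse_end: int  # contig coordinate of amplicon 3' end (half-open)

    ok = True

    @property
    def forward_tailed(self) -> str:
        return TAIL + self.forward_core


@dataclass(frozen=True)
class PrimerFailure:
    """Why no pair was feasible: tally of first-failed constraints."""

    reason: str
    tally: dict[str, int]

    ok = False

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return False


def _window_check(word: str, c: PrimerConstraints) -> str | None:
    """First failed constraint name, or None when the window is usable."""
    if "N" in word:
        return "N"
    gc = gc_fraction(word)
    if not (c.gc_min <= gc <= c.gc_max):
        return "gc"
    tm = melting_temp(word)
    if not (c.tm_min <= tm <= c.tm_max):
        return "tm"
    if _max_mono_run(word) > c.max_mono_run:
        return "mono_run"
    if word[-1] not in "GC":
        return "3prime_gc"
    return None


def design_primer_pair(
    locus: SSRLocus,
    contigs: ContigSet,
    constraints: PrimerConstraints | None = None,
) -> PrimerPair | PrimerFailure:
    """Search the flanks of ``locus`` for a feasible primer pair.

    Candidate forward windows lie entirely in the left flank, reverse windows
    (reverse-complemented) entirely in the right flank, so the amplicon always
    spans the full tract.  Among feasible pairs the smallest size bin wins,
    then minimal Tm difference, then the shorter amplicon, then the leftmost
    forward start — the choice is fully deterministic.
    """
    c = constraints or PrimerConstraints()
    seq = contigs.sequence(locus.contig_id)
    start, end = locus.span
    lo_len, hi_len = PRIMER_LEN_RANGE
    max_amp = SIZE_BINS[-1][1]
    tally: Counter[str] = Counter()

    # forward candidates: windows ending at or before the tract start
    forward: list[tuple[int, str, float]] = []  # (start, word, tm)
    scan_left = max(0, start - max_amp)
    for w_end in range(start, scan_left + lo_len - 1, -1):
        for length in range(lo_len, hi_len + 1):
            w_start = w_end - length
            if w_start < scan_left or w_start < 0:
                continue
            word = seq[w_start:w_end]
            fail = _window_check(word, c)
            if fail is None:
                forward.append((w_start, word, melting_temp(word)))
            else:
                tally[f"forward_{fail}"] += 1

    # reverse candidates: windows starting at or after the tract end
    reverse: list[tuple[int, str, float]] = []  # (end_coord, core, tm)
    scan_right = min(len(seq), end + max_amp)
    for w_start in range(end, scan_right - lo_len + 1):
        for length in range(lo_len, hi_len + 1):
            w_end = w_start + length
            if w_end > scan_right:
                continue
            core = reverse_complement(seq[w_start:w_end])
            fail = _window_check(core, c)
            if fail is None:
                reverse.append((w_end, core, melting_temp(core)))
            else:
                tally[f"reverse_{fail}"] += 1

    if not forward or not reverse:
        side = "forward" if not forward else "reverse"
        reason = _dominant(tally, side) or f"{side}_no_window"
        return PrimerFailure(reason, dict(tally))

    best: tuple | None = None  # (bin_idx, dTm, amp_len, f_start, pair parts)
    for f_start, f_word, f_tm in forward:
        for r_end, r_core, r_tm in reverse:
            amp = r_end - f_start
            bin_idx = _bin_index(amp)
            if bin_idx is None:
                tally["amplicon_bin"] += 1
                continue
            d_tm = abs(f_tm - r_tm)
            if d_tm > c.max_tm_diff:
                tally["tm_diff"] += 1
                continue
            key = (bin_idx, d_tm, amp, f_start)
            if best is None or key < best[0]:
                best = (key, (f_start, f_word, f_tm, r_end, r_core, r_tm, amp, bin_idx))
    if best is None:
        reason = "amplicon_bin" if tally.get("amplicon_bin") else "tm_diff"
        return PrimerFailure(reason, dict(tally))

    f_start, f_word, f_tm, r_end, r_core, r_tm, amp, bin_idx = best[1]
    return PrimerPair(
        forward_core=f_word,
        reverse_core=r_core,
        tm_forward=f_tm,
        tm_reverse=r_tm,
        gc_forward=gc_fraction(f_word),
        gc_reverse=gc_fraction(r_core),
        amplicon_length=amp,
        size_bin=SIZE_BINS[bin_idx],
        forward_start=f_start,
        reverse_end=r_end,
    )


def _bin_index(amplicon: int) -> int | None:
    for i, (lo, hi) in enumerate(SIZE_BINS):
        if lo <= amplicon <= hi:
            return i
    return None


def _dominant(tally: Counter, side: str) -> str | None:
    sided = {k: v for k, v in tally.items() if k.startswith(side)}
    if not sided:
        return None
    return max(sided, key=sided.get)
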