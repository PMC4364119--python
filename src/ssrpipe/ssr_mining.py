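"""Microsatellite (SSR) detection and pruning on assembled contigs.

The detector reports every *maximal perfect tandem tract* whose primitive
period lies in a configured range (2–5 by default; homopolymers excluded, as
their apparent length is unreliable on pyrosequencing platforms, and
hexanucleotides fall outside the period cap).  Neighbouring tracts on a
contig separated by less than a gap threshold are merged into a single
compound locus, and loci are then pruned to Potential Amplifiable Loci (PAL):
at least one component with five or more full repeat units, at least 30 bp of
flanking sequence on both sides, and a feasible primer pair.

A perfect tandem tract is a run ``s[i:j]`` with ``s[k] == s[k+p]`` for all
``k`` in ``[i, j-p)``; it is *maximal* when it can be extended in neither
direction, and it is reported under its primitive period only (the motif is
not a whole-number power of a shorter word).  Partial trailing units are part
of the span but do not count toward the unit tally.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .io_formats import ContigSet


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds for detection and PAL pruning.

    ``min_tract_length`` is the floor on total tract span (partial unit
    included); the detection floor of 5 full units and the 15 bp length floor
    together emulate a score-threshold tandem-repeat screen on perfect
    repeats.
    """

    min_period: int = 2
    max_period: int = 5
    min_repeats_detect: int = 5
    min_tract_length: int = 15
    exclude_homopolymers: bool = True
    max_gap_compound: int = 100
    min_repeats_pal: int = 5
    min_flank: int = 30

    def __post_init__(self) -> None:
        if not (1 <= self.min_period <= self.max_period <= 6):
            raise ValueError("periods must satisfy 1 <= min <= max <= 6")
        for name in ("min_repeats_detect", "min_tract_length",
                     "max_gap_compound", "min_repeats_pal", "min_flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SSRComponent:
    """One perfect tract: observed motif (phase at tract start), its
    rotation-canonical form, full-unit count, and 0-based half-open span."""

    motif: str
    canonical: str
    period: int
    repeats: int
    span: tuple[int, int]


@dataclass(frozen=True)
class SSRLocus:
    """A detected SSR locus, possibly compound.

    ``span`` covers all components including inter-component gaps; flanks are
    measured to the contig ends.
    """

    contig_id: str
    span: tuple[int, int]
    components: tuple[SSRComponent, ...]
    left_flank: int
    right_flank: int

    @property
    def is_compound(self) -> bool:
        return len(self.components) > 1

    @property
    def motif_string(self) -> str:
        """Human-readable structure, e.g. ``[TAA]11 4 [ATT]5``."""
        parts: list[str] = []
        prev_end: int | None = None
        for c in self.components:
            if prev_end is not None:
                parts.append(str(c.span[0] - prev_end))
            parts.append(f"[{c.motif}]{c.repeats}")
            prev_end = c.span[1]
        return " ".join(parts)

    @property
    def max_repeats(self) -> int:
        return max(c.repeats for c in self.components)

    @property
    def first_period(self) -> int:
        return self.components[0].period


def canonical_motif(word: str) -> tuple[str, bool]:
    """Lexicographically smallest rotation of ``word`` and a primitivity flag.

    A word is primitive when it is not a whole-number power of a strictly
    shorter word (``"ATAT"`` is ``"AT"**2`` and therefore not primitive).
    """
    if not word or len(word) > 6:
        raise ValueError("motif length must be 1-6")
    if set(word) - set("ACGT"):
        raise ValueError(f"illegal character in motif {word!r}")
    canon = min(word[i:] + word[:i] for i in range(len(word)))
    primitive = True
    n = len(word)
    for d in range(1, n):
        if n % d == 0 and word[:d] * (n // d) == word:
            primitive = False
            break
    return canon, primitive


def _maximal_tracts(seq: str, period: int) -> Iterable[tuple[int, int]]:
    """Maximal runs where ``seq[k] == seq[k+period]``, as half-open spans.

    N never matches anything, so tracts cannot cross ambiguous bases.
    """
    n = len(seq)
    if n < 2 * period:
        return
    k = 0
    limit = n - period
    while k < limit:
        if seq[k] != "N" and seq[k] == seq[k + period]:
            start = k
            while k < limit and seq[k] != "N" and seq[k] == seq[k + period]:
                k += 1
            yield start, k + period
        else:
            k += 1


def find_ssrs(contigs: ContigSet, config: DetectorConfig | None = None) -> list[SSRLocus]:
    """Detect all maximal perfect tandem tracts passing the config thresholds.

    Each tract is reported exactly once under its primitive period; a tract
    whose first full unit is a power of a shorter word belongs to that shorter
    period and is suppressed here, which also removes homopolymer disguises
    such as ``AA`` at period 2.
    """
    config = config or DetectorConfig()
    out: list[SSRLocus] = []
    lo = max(1, config.min_period)
    for contig_id, seq in contigs:
        n = len(seq)
        found: list[SSRComponent] = []
        for period in range(lo, config.max_period + 1):
            for start, end in _maximal_tracts(seq, period):
                length = end - start
                repeats = length // period
                if repeats < config.min_repeats_detect:
                    continue
                if length < config.min_tract_length:
                    continue
                motif = seq[start:start + period]
                canon, primitive = canonical_motif(motif)
                if not primitive:
                    continue  # reported at its primitive period instead
                if period == 1 and config.exclude_homopolymers:
                    continue
                found.append(SSRComponent(motif, canon, period, repeats, (start, end)))
        found.sort(key=lambda c: (c.span, c.period))
        for comp in found:
            out.append(
                SSRLocus(
                    contig_id=contig_id,
                    span=comp.span,
                    components=(comp,),
                    left_flank=comp.span[0],
                    right_flank=n - comp.span[1],
                )
            )
    return out


def merge_compound(ssrs: Sequence[SSRLocus], config: DetectorConfig | None = None) -> list[SSRLocus]:
    """Collapse runs of neighbouring same-contig loci into compound loci.

    Adjacent loci with gap strictly less than ``max_gap_compound`` chain
    transitively; component order is positional.  Overlapping input spans are
    an error (the detector never produces overlapping reports of one tract,
    and distinct interleaved tracts cannot form a well-ordered compound).
    """
    config = config or DetectorConfig()
    by_contig: dict[str, list[SSRLocus]] = {}
    for locus in ssrs:
        by_contig.setdefault(locus.contig_id, []).append(locus)
    out: list[SSRLocus] = []
    for contig_id in by_contig:
        loci = sorted(by_contig[contig_id], key=lambda l: l.span)
        run: list[SSRLocus] = []
        for locus in loci:
            if run and locus.span[0] < run[-1].span[1]:
                raise ValueError(
                    f"overlapping SSR spans on {contig_id}: "
                    f"{run[-1].span} and {locus.span}"
                )
            if run and locus.span[0] - run[-1].span[1] < config.max_gap_compound:
                run.append(locus)
            else:
                if run:
                    out.append(_collapse(run))
                run = [locus]
        if run:
            out.append(_collapse(run))
    out.sort(key=lambda l: (l.contig_id, l.span))
    return out


def _collapse(run: list[SSRLocus]) -> SSRLocus:
    if len(run) == 1:
        return run[0]
    components = tuple(c for locus in run for c in locus.components)
    span = (run[0].span[0], run[-1].span[1])
    first = run[0]
    contig_len = first.left_flank + (first.span[1] - first.span[0]) + first.right_flank
    return SSRLocus(
        contig_id=first.contig_id,
        span=span,
        components=components,
        left_flank=span[0],
        right_flank=contig_len - span[1],
    )


@dataclass
class Rejection:
    locus: SSRLocus
    reason: str


def filter_pal(
    ssrs: Sequence[SSRLocus],
    contigs: ContigSet,
    config: DetectorConfig | None = None,
    primer_check: Callable[[SSRLocus, ContigSet], object] | None = None,
) -> tuple[list, list[Rejection]]:
    """Prune compound-merged loci to Potential Amplifiable Loci.

    Retention requires (a) some component with >= ``min_repeats_pal`` full
    units, (b) both flanks >= ``min_flank`` bp, and (c) a feasible primer
    pair.  Returns ``(pal_list, rejection_log)``; every input locus lands in
    exactly one of the two.  PAL entries are ``(locus, primer_pair)`` tuples.
    """
    config = config or DetectorConfig()
    if primer_check is None:
        from .primer_feasibility import design_primer_pair

        def primer_check(locus, ctgs):  # noqa: F811 - default hook
            return design_primer_pair(locus, ctgs)

    pal: list[tuple[SSRLocus, object]] = []
    rejects: list[Rejection] = []
    for locus in ssrs:
        if locus.max_repeats < config.min_repeats_pal:
            rejects.append(Rejection(locus, "min_repeats"))
            continue
        if locus.left_flank < config.min_flank or locus.right_flank < config.min_flank:
            rejects.append(Rejection(locus, "flank"))
            continue
        result = primer_check(locus, contigs)
        if getattr(result, "ok", bool(result)):
            pal.append((locus, result))
        else:
            reason = getattr(result, "reason", "primer")
            rejects.append(Rejection(locus, f"primer:{reason}"))
    return pal, rejects


PERIOD_LABELS = {2: "di", 3: "tri", 4: "tetra", 5: "penta"}


def classify_periods(ssrs: Sequence[SSRLocus]) -> dict[str, tuple[int, float]]:
    """Count loci by period class; compound loci go by their first component.

    Returns ``{label: (count, percentage)}``; percentages are zero on empty
    input.
    """
    counts = Counter()
    for locus in ssrs:
        period = locus.first_period
        if period not in PERIOD_LABELS:
            raise ValueError(f"period {period} outside 2-5")
        counts[period] += 1
    total = sum(counts.values())
    return {
        label: (counts[p], 100.0 * counts[p] / total if total else 0.0)
        for p, label in PERIOD_LABELS.items()
    }


def ssr_density(n_ssrs: int, total_bases: int) -> tuple[float, float]:
    """SSR density per Kb and per Mb of contig sequence."""
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    per_kb = 1000.0 * n_ssrs / total_bases
    return per_kb, per_kb * 1000.0
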