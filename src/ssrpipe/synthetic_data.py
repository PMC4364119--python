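"""Synthetic test beds for the whole pipeline.

Two generators:

* :func:`generate_genome` builds random contigs with tandem-repeat tracts
  planted at known positions (optionally compound, i.e. several tracts with
  short gaps), returning a ground-truth table.  The background is i.i.d.
  uniform DNA and is *repeat-sanitized*: any unintended perfect tract of
  period 1-5 that would reach detection thresholds is re-sampled, so planted
  tracts are the only detectable repeats and recall/precision can be scored
  exactly.

* :func:`generate_genotypes` draws multi-population diploid genotypes from a
  Balding–Nichols island model: per locus, ancestral allele frequencies come
  from a flat Dirichlet and population frequencies from
  ``Dirichlet(p_anc * (1-F)/F)``, so ``F`` is the expected Weir-Cockerham
  differentiation.  A per-gamete null-allele mechanism mirrors amplification
  failure: null homozygotes become missing data, heterozygous carriers are
  recorded as homozygous for the visible allele.

All randomness flows from a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, ContigSet, GenotypeDataset
from .ssr_mining import DetectorConfig, find_ssrs

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantSpec:
    """A tract (or compound tract) to plant into a contig.

    ``components`` is a list of ``(motif, repeats, gap_before)`` tuples; the
    first gap is ignored.  A simple plant is one component.
    """

    contig_index: int
    position: int
    components: tuple[tuple[str, int, int], ...]

    @staticmethod
    def simple(contig_index: int, position: int, motif: str, repeats: int) -> "PlantSpec":
        return PlantSpec(contig_index, position, ((motif, repeats, 0),))

    def spans(self) -> list[tuple[int, int, str, int]]:
        """Per-component ``(start, end, motif, repeats)`` within the contig."""
        out = []
        pos = self.position
        for i, (motif, repeats, gap) in enumerate(self.components):
            if repeats < 2:
                raise ValueError("planted tracts need >= 2 repeats")
            if i > 0:
                if gap < 0:
                    raise ValueError("gaps must be >= 0")
                pos += gap
            end = pos + len(motif) * repeats
            out.append((pos, end, motif, repeats))
            pos = end
        return out

    @property
    def total_span(self) -> tuple[int, int]:
        spans = self.spans()
        return spans[0][0], spans[-1][1]


def generate_genome(
    n_contigs: int,
    contig_length: int,
    plants: list[PlantSpec],
    seed: int,
    sanitize_config: DetectorConfig | None = None,
    max_sanitize_rounds: int = 200,
) -> tuple[ContigSet, pd.DataFrame]:
    """Random contigs with planted SSR tracts and a ground-truth table.

    The truth table has one row per planted component with 0-based half-open
    spans.  Plants must not overlap and must fit their contig.  Sanitization
    re-samples background positions belonging to any unintended tract that a
    slightly-permissive detector would report, including tracts that extend a
    plant past its boundary; planted bases are never touched.
    """
    rng = np.random.default_rng(seed)
    # permissive thresholds: sanitize anything close to detectable
    scfg = sanitize_config or DetectorConfig(
        min_period=1,
        max_period=5,
        min_repeats_detect=4,
        min_tract_length=8,
        exclude_homopolymers=False,
    )
    seqs = [rng.integers(0, 4, size=contig_length) for _ in range(n_contigs)]

    planted: dict[int, list[tuple[int, int, str, int]]] = {i: [] for i in range(n_contigs)}
    truth_rows = []
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for plant in plants:
        ci = plant.contig_index
        if ci < 0 or ci >= n_contigs:
            raise ValueError(f"plant contig index {ci} out of range")
        for start, end, motif, repeats in plant.spans():
            if end > contig_length or start < 0:
                raise ValueError("plant exceeds contig bounds")
            for ps, pe, *_ in planted[ci]:
                if start < pe and ps < end:
                    raise ValueError("planted tracts overlap")
            tract = (motif * repeats)
            seqs[ci][start:end] = [base_idx[b] for b in tract]
            planted[ci].append((start, end, motif, repeats))
            truth_rows.append(
                {
                    "contig_id": f"contig{ci}",
                    "start": start,
                    "end": end,
                    "motif": motif,
                    "repeats": repeats,
                }
            )
    for ci in planted:
        planted[ci].sort()

    protected: dict[int, np.ndarray] = {}
    for ci in range(n_contigs):
        mask = np.zeros(contig_length, dtype=bool)
        for start, end, *_ in planted[ci]:
            mask[start:end] = True
        protected[ci] = mask

    truth_spans = {
        ci: {(s, e) for s, e, _, _ in planted[ci]} for ci in range(n_contigs)
    }

    def to_str(arr: np.ndarray) -> str:
        return "".join(BASES[arr])

    for ci in range(n_contigs):
        for _ in range(max_sanitize_rounds):
            contig = ContigSet([(f"contig{ci}", to_str(seqs[ci]))])
            dirty = []
            for locus in find_ssrs(contig, scfg):
                if locus.span in truth_spans[ci]:
                    continue
                dirty.append(locus.span)
            if not dirty:
                break
            for start, end in dirty:
                resample = np.arange(start, end)
                resample = resample[~protected[ci][resample]]
                if resample.size == 0:
                    # fully inside plants: a gap-free artefact; widen by one
                    continue
                seqs[ci][resample] = rng.integers(0, 4, size=resample.size)
        else:
            raise RuntimeError("background sanitization did not converge")

    contigs = ContigSet([(f"contig{i}", to_str(seqs[i])) for i in range(n_contigs)])
    truth = pd.DataFrame(
        truth_rows, columns=["contig_id", "start", "end", "motif", "repeats"]
    )
    return contigs, truth


# ---------------------------------------------------------------------------
# genotypes


@dataclass(frozen=True)
class IslandModelSpec:
    """Balding–Nichols island-model sampling design.

    ``fst`` is the target differentiation (0 gives identical expected
    frequencies in every population); ``null_rate`` is the per-gamete null
    allele probability at every locus.
    """

    n_pops: int = 6
    n_per_pop: int = 8
    n_loci: int = 14
    n_alleles: int = 5
    fst: float = 0.05
    null_rate: float = 0.0
    seed: int = 0
    n_groups: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if not (0.0 <= self.null_rate < 1.0):
            raise ValueError("null_rate must lie in [0, 1)")
        if min(self.n_pops, self.n_per_pop, self.n_loci, self.n_alleles) < 1:
            raise ValueError("design sizes must be positive")
        if not (1 <= self.n_groups <= self.n_pops):
            raise ValueError("n_groups must lie in [1, n_pops]")


def allele_size(index: int) -> int:
    """Fragment size (bp) for synthetic allele ``index`` on a dinucleotide
    ladder starting at 100 bp."""
    return 100 + 2 * index


def generate_genotypes(spec: IslandModelSpec) -> tuple[GenotypeDataset, dict]:
    """Draw a multi-population diploid dataset under the island model.

    Returns the dataset (alleles coded as fragment sizes) and a truth dict
    with ancestral and per-population allele frequencies and the null-gamete
    record.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_alleles
    ancestral = rng.dirichlet(np.ones(k), size=spec.n_loci)  # (loci, alleles)
    pop_freqs = np.empty((spec.n_pops, spec.n_loci, k))
    if spec.fst == 0.0:
        pop_freqs[:] = ancestral[None, :, :]
    else:
        scale = (1.0 - spec.fst) / spec.fst
        for p in range(spec.n_pops):
            for l in range(spec.n_loci):
                pop_freqs[p, l] = rng.dirichlet(ancestral[l] * scale)

    sizes = np.array([allele_size(i) for i in range(k)])
    n_ind = spec.n_per_pop
    # gametes drawn per (pop, locus) by inverse-CDF so draws vectorize
    gam = np.empty((spec.n_pops, n_ind, spec.n_loci, 2), dtype=np.int64)
    for p in range(spec.n_pops):
        for l in range(spec.n_loci):
            cdf = np.cumsum(pop_freqs[p, l])
            cdf[-1] = 1.0
            u = rng.random((n_ind, 2))
            gam[p, :, l, :] = np.searchsorted(cdf, u, side="right")
    null_mask = rng.random(gam.shape) < spec.null_rate

    genotypes: list[list[list[tuple[int, int]]]] = []
    individual_names: list[list[str]] = []
    for p in range(spec.n_pops):
        pop: list[list[tuple[int, int]]] = []
        names: list[str] = []
        for i in range(n_ind):
            row: list[tuple[int, int]] = []
            for l in range(spec.n_loci):
                nulls = null_mask[p, i, l]
                g = gam[p, i, l]
                if nulls.all():
                    row.append((MISSING, MISSING))
                elif nulls.any():
                    visible = int(g[~nulls][0])
                    row.append((int(sizes[visible]), int(sizes[visible])))
                else:
                    row.append((int(sizes[g[0]]), int(sizes[g[1]])))
            pop.append(row)
            names.append(f"pop{p + 1}_ind{i + 1}")
        genotypes.append(pop)
        individual_names.append(names)

    group_ids = [f"basin{(p * spec.n_groups) // spec.n_pops + 1}" for p in range(spec.n_pops)]
    dataset = GenotypeDataset(
        locus_names=[f"locus{l + 1}" for l in range(spec.n_loci)],
        pop_names=[f"pop{p + 1}" for p in range(spec.n_pops)],
        individual_names=individual_names,
        genotypes=genotypes,
        group_ids=group_ids,
        title=f"ssrpipe island model fst={spec.fst} seed={spec.seed}",
    )
    truth = {
        "ancestral_freqs": ancestral,
        "pop_freqs": pop_freqs,
        "null_mask": null_mask,
        "allele_sizes": sizes,
        "spec": spec,
    }
    return dataset, truth
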