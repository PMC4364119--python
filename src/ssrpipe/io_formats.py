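"""Readers and writers for the pipeline's on-disk formats.

Three formats travel through the pipeline: multi-record FASTA for assembled
contigs, the GenePop text dialect for diploid multilocus genotypes (alleles
coded as fragment sizes in base pairs), and header-row TSV for every tabular
report.  Coordinates are 0-based half-open everywhere in memory; reports that
print 1-based inclusive spans label them as such.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.PopGen.GenePop import read as _genepop_read
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")
MISSING = 0  # allele code for missing data


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ContigSet:
    """A set of assembled contigs.

    Sequences are uppercase DNA over {A,C,G,T,N}; contig ids are unique and
    ``total_bases`` equals the summed sequence length.
    """

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, seq in self.records:
            if cid in seen:
                raise FormatError(f"duplicate contig id {cid!r}")
            seen.add(cid)
            if not seq:
                raise FormatError(f"empty sequence for contig {cid!r}")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"illegal character(s) {sorted(bad)} in contig {cid!r}"
                )

    @property
    def total_bases(self) -> int:
        return sum(len(seq) for _, seq in self.records)

    @property
    def ids(self) -> list[str]:
        return [cid for cid, _ in self.records]

    def sequence(self, contig_id: str) -> str:
        for cid, seq in self.records:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class GenotypeDataset:
    """Diploid allele-size genotypes for individuals grouped into populations.

    ``genotypes[p][i][l]`` is the ``(a1, a2)`` pair of allele codes for
    individual ``i`` of population ``p`` at locus ``l``; positive codes are
    fragment sizes in bp, ``(0, 0)`` is missing.  Each population optionally
    carries a group id (e.g. a hydrographic basin) for two-level analyses.
    """

    locus_names: list[str]
    pop_names: list[str]
    individual_names: list[list[str]]
    genotypes: list[list[list[tuple[int, int]]]]
    group_ids: list[str] | None = None
    title: str = "ssrpipe dataset"
    marker_len: int = 3  # GenePop digit width, recorded for faithful re-write

    def __post_init__(self) -> None:
        if len(self.pop_names) != len(self.genotypes):
            raise FormatError("pop_names and genotypes length mismatch")
        if self.group_ids is not None and len(self.group_ids) != len(self.pop_names):
            raise FormatError("group_ids must cover every population")
        n_loci = len(self.locus_names)
        for pop, inds in zip(self.pop_names, self.genotypes):
            for ind in inds:
                if len(ind) != n_loci:
                    raise FormatError(
                        f"individual in pop {pop!r} has {len(ind)} genotypes, "
                        f"expected {n_loci}"
                    )
                for a1, a2 in ind:
                    if (a1 == MISSING) != (a2 == MISSING):
                        raise FormatError(
                            f"half-missing genotype ({a1},{a2}) in pop {pop!r}"
                        )

    @property
    def n_pops(self) -> int:
        return len(self.pop_names)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def n_individuals(self) -> int:
        return sum(len(p) for p in self.genotypes)

    def locus_index(self, locus: str) -> int:
        return self.locus_names.index(locus)

    def pop_index(self, pop: str) -> int:
        return self.pop_names.index(pop)

    def locus_genotypes(self, locus_idx: int, pop_idx: int) -> list[tuple[int, int]]:
        """Non-missing genotypes at one locus in one population."""
        return [
            g[locus_idx]
            for g in self.genotypes[pop_idx]
            if g[locus_idx][0] != MISSING
        ]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> ContigSet:
    """Read a multi-record FASTA into a :class:`ContigSet`.

    Sequences are uppercased; characters outside {A,C,G,T,N} and duplicate
    ids are rejected.
    """
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return ContigSet(records)


def write_fasta(contigs: ContigSet, path: str | Path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in contigs.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# GenePop


def read_genepop(path: str | Path) -> GenotypeDataset:
    """Parse a GenePop file (2- or 3-digit dialect auto-detected).

    Population order and individual order are preserved; the all-zero code is
    missing.  Half-missing genotypes (one allele coded zero) are rejected.
    """
    text = Path(path).read_text()
    if not any(line.strip().lower() == "pop" for line in text.splitlines()):
        raise FormatError(f"{path}: no 'Pop' delimiter line")
    try:
        rec = _genepop_read(io.StringIO(text))
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed GenePop file ({exc})") from exc
    title = text.splitlines()[0].strip()
    pop_names: list[str] = []
    individual_names: list[list[str]] = []
    genotypes: list[list[list[tuple[int, int]]]] = []
    n_loci = len(rec.loci_list)
    for p, pop in enumerate(rec.populations):
        pop_names.append(f"pop{p + 1}")
        names: list[str] = []
        inds: list[list[tuple[int, int]]] = []
        for ind_name, alleles in pop:
            if len(alleles) != n_loci:
                raise FormatError(
                    f"{path}: individual {ind_name!r} has {len(alleles)} "
                    f"genotypes for {n_loci} loci"
                )
            row: list[tuple[int, int]] = []
            for a1, a2 in alleles:
                a1 = MISSING if a1 is None else a1
                a2 = MISSING if a2 is None else a2
                if (a1 == MISSING) != (a2 == MISSING):
                    raise FormatError(
                        f"{path}: half-missing genotype for {ind_name!r}"
                    )
                row.append((a1, a2))
            names.append(ind_name.strip())
            inds.append(row)
        individual_names.append(names)
        genotypes.append(inds)
    return GenotypeDataset(
        locus_names=list(rec.loci_list),
        pop_names=pop_names,
        individual_names=individual_names,
        genotypes=genotypes,
        title=title,
        marker_len=rec.marker_len,
    )


def write_genepop(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write a GenePop file in the dataset's recorded digit width.

    Ordering is the input ordering; missing genotypes are written as the
    all-zero code.  Allele codes that do not fit the digit width are an error.
    """
    width = dataset.marker_len
    limit = 10**width
    if dataset.n_pops == 0:
        raise FormatError("cannot write GenePop file with no populations")
    lines = [dataset.title]
    lines.extend(dataset.locus_names)
    for pop_idx in range(dataset.n_pops):
        lines.append("Pop")
        for name, genos in zip(
            dataset.individual_names[pop_idx], dataset.genotypes[pop_idx]
        ):
            fields = []
            for a1, a2 in genos:
                if a1 >= limit or a2 >= limit:
                    raise FormatError(
                        f"allele code {max(a1, a2)} does not fit "
                        f"{width}-digit GenePop coding"
                    )
                fields.append(f"{a1:0{width}d}{a2:0{width}d}")
            lines.append(f"{name} , " + " ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def write_groups_tsv(dataset: GenotypeDataset, path: str | Path) -> None:
    """Sidecar TSV mapping each population to its group (basin)."""
    groups = dataset.group_ids or ["group1"] * dataset.n_pops
    lines = ["pop\tgroup"]
    lines += [f"{p}\t{g}" for p, g in zip(dataset.pop_names, groups)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["pop", "group"]:
        raise FormatError(f"{path}: expected header 'pop\\tgroup'")
    mapping: dict[str, str] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        pop, group = line.split("\t")[:2]
        mapping[pop] = group
    return mapping


def to_one_based(span: tuple[int, int]) -> tuple[int, int]:
    """Convert a 0-based half-open span to 1-based inclusive for display."""
    start, end = span
    return start + 1, end
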