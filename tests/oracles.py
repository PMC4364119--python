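"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — exhaustive enumeration or direct
summation at tiny problem sizes — and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


# ---------------------------------------------------------------------------
# tandem-repeat tracts


def brute_force_tracts(
    seq: str,
    min_period: int = 2,
    max_period: int = 5,
    min_repeats: int = 5,
    min_length: int = 15,
    exclude_homopolymers: bool = True,
) -> set[tuple[int, int, int]]:
    """All maximal perfect tandem tracts as (start, end, primitive_period).

    A tract s[start:end] satisfies s[k] == s[k-p] for k in [start+p, end),
    contains no N, cannot be extended either way, and its first unit is not a
    power of a shorter word.
    """
    n = len(seq)
    out: set[tuple[int, int, int]] = set()
    lo = 1 if not exclude_homopolymers else min(min_period, 1)
    for p in range(1, max_period + 1):
        for start in range(n - 2 * p + 1):
            # left-maximality
            if start > 0 and seq[start - 1] != "N" and seq[start - 1] == seq[start - 1 + p]:
                continue
            end = start + p
            if "N" in seq[start:end]:
                continue
            while end < n and seq[end] != "N" and seq[end] == seq[end - p]:
                end += 1
            length = end - start
            if length < 2 * p:
                continue
            motif = seq[start:start + p]
            if not _is_primitive(motif):
                continue
            if p == 1 and exclude_homopolymers:
                continue
            if p < min_period:
                continue
            if length // p < min_repeats or length < min_length:
                continue
            out.add((start, end, p))
    return out


def _is_primitive(motif: str) -> bool:
    p = len(motif)
    for q in range(1, p):
        if p % q == 0 and motif == motif[:q] * (p // q):
            return False
    return True


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test by exhaustive gene pairing


def hwe_pairing_oracle(genotypes: list[tuple[int, int]]) -> float:
    """Exact probability-test p-value by enumerating every perfect matching
    of the labelled gene copies (feasible up to ~6 individuals).

    Each matching of the 2n labelled genes into n pairs is equally likely
    under the null; the probability of a genotype table is the fraction of
    matchings producing it, and the p-value sums the probabilities of tables
    no more probable than the observed one.
    """
    genes: list[int] = []
    obs_table: Counter = Counter()
    for a1, a2 in genotypes:
        genes.extend([a1, a2])
        obs_table[(min(a1, a2), max(a1, a2))] += 1
    if len(set(genes)) < 2:
        return 1.0

    table_counts: Counter = Counter()

    def matchings(remaining: tuple[int, ...], table: tuple):
        if not remaining:
            table_counts[tuple(sorted(table))] += 1
            return
        first = remaining[0]
        for idx in range(1, len(remaining)):
            partner = remaining[idx]
            pair = (min(first, partner), max(first, partner))
            rest = remaining[1:idx] + remaining[idx + 1:]
            matchings(rest, table + (pair,))

    matchings(tuple(genes), ())
    total = sum(table_counts.values())
    obs_key = tuple(
        sorted(pair for pair, cnt in obs_table.items() for _ in range(cnt))
    )
    obs_prob = table_counts[obs_key]
    return sum(c for c in table_counts.values() if c <= obs_prob) / total


# ---------------------------------------------------------------------------
# Weir-Cockerham theta, scalar re-derivation for 2 pops / 1 locus


def wc_theta_two_pop_oracle(
    pop1: list[tuple[int, int]], pop2: list[tuple[int, int]]
) -> float:
    """Theta for two populations at one locus, coded directly from the
    variance-component definitions (per allele, then ratio of sums)."""
    pops = [pop1, pop2]
    alleles = sorted({a for pop in pops for g in pop for a in g})
    n = [len(pop) for pop in pops]
    r = 2
    nbar = (n[0] + n[1]) / r
    nc = (r * nbar - (n[0] ** 2 + n[1] ** 2) / (r * nbar)) / (r - 1)
    sum_a = sum_abc = 0.0
    for allele in alleles:
        p = []
        h = []
        for pop in pops:
            copies = sum(int(g[0] == allele) + int(g[1] == allele) for g in pop)
            hets = sum(1 for g in pop if (g[0] == allele) != (g[1] == allele))
            p.append(copies / (2 * len(pop)))
            h.append(hets / len(pop))
        pbar = (n[0] * p[0] + n[1] * p[1]) / (r * nbar)
        s2 = (n[0] * (p[0] - pbar) ** 2 + n[1] * (p[1] - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n[0] * h[0] + n[1] * h[1]) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


# ---------------------------------------------------------------------------
# AMOVA sums of squares from the explicit pairwise distance matrix


def amova_ssd_oracle(
    gene_alleles: list[int], gene_pop: list[int], pop_group: list[int]
) -> dict[str, float]:
    """SSDs for a single locus computed from the full 0/1 distance matrix.

    SS of a set = sum of pairwise squared distances within the set divided
    by the set size.
    """
    m = len(gene_alleles)
    d2 = [
        [0 if gene_alleles[i] == gene_alleles[j] else 1 for j in range(m)]
        for i in range(m)
    ]

    def ss(members: list[int]) -> float:
        if not members:
            return 0.0
        tot = 0.0
        for i, j in itertools.combinations(members, 2):
            tot += d2[i][j]
        return tot / len(members)

    pops = sorted(set(gene_pop))
    groups = sorted(set(pop_group))
    ss_pops = sum(ss([i for i in range(m) if gene_pop[i] == p]) for p in pops)
    ss_groups = sum(
        ss([i for i in range(m) if pop_group[gene_pop[i]] == g]) for g in groups
    )
    ss_total = ss(list(range(m)))
    return {
        "ssd_wp": ss_pops,
        "ssd_ap": ss_groups - ss_pops,
        "ssd_ag": ss_total - ss_groups,
        "ssd_total": ss_total,
    }


# ---------------------------------------------------------------------------
# allelic richness by exhaustive subsampling


def rarefaction_oracle(counts: list[int], g: int) -> float:
    """Mean number of distinct alleles over all C(N, g) subsamples of the
    labelled gene copies."""
    genes = [i for i, c in enumerate(counts) for _ in range(c)]
    total = 0
    n_sub = 0
    for combo in itertools.combinations(range(len(genes)), g):
        total += len({genes[i] for i in combo})
        n_sub += 1
    return total / n_sub


# ---------------------------------------------------------------------------
# descriptive statistics, two-pass


def describe_oracle(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)
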