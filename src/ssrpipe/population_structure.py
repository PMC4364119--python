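"""Multi-population inference on diploid microsatellite genotypes.

Three analyses:

* Weir & Cockerham's (1984) theta — the variance-components FST estimator —
  globally, per locus, and for population pairs with permutation
  significance (ratio-of-sums aggregation across alleles and loci).
* Three-level AMOVA (within populations / among populations within groups /
  among groups) on 0/1 allele-identity distances between gene copies, with
  Phi statistics and level-appropriate permutation tests.
* An admixture-model Gibbs sampler in the STRUCTURE family, with independent
  (flat-Dirichlet) allele-frequency priors, an ln P(D) estimate via the
  mean-minus-half-variance approximation of the posterior deviance, and a
  parsimony rule for choosing the number of clusters K.

Everything is seed-deterministic: identical inputs and seeds give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeDataset
from .locus_stats import by_fdr

# ---------------------------------------------------------------------------
# array representation


def dataset_arrays(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a dataset to ``(alleles, pops)``.

    ``alleles`` is ``(n_individuals, n_loci, 2)`` with -1 for missing;
    ``pops`` is the population index of each individual.
    """
    rows = []
    pop_idx = []
    for p, pop in enumerate(dataset.genotypes):
        for ind in pop:
            rows.append([[a1 if a1 != MISSING else -1, a2 if a2 != MISSING else -1]
                         for a1, a2 in ind])
            pop_idx.append(p)
    return np.asarray(rows, dtype=np.int64), np.asarray(pop_idx, dtype=np.int64)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta


def _theta_sums(alleles: np.ndarray, pops: np.ndarray, n_pops: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (sum_a, sum_abc) of Weir-Cockerham components.

    For each locus and segregating allele, computes the among-population (a),
    among-individual (b) and within-individual (c) components from sample
    sizes, frequency variance and observed heterozygote frequencies, then
    sums over alleles.
    """
    n_loci = alleles.shape[1]
    sums_a = np.zeros(n_loci)
    sums_abc = np.zeros(n_loci)
    for l in range(n_loci):
        a1 = alleles[:, l, 0]
        a2 = alleles[:, l, 1]
        valid = a1 >= 0
        if valid.sum() == 0:
            continue
        pv = pops[valid]
        v1, v2 = a1[valid], a2[valid]
        n_i = np.bincount(pv, minlength=n_pops).astype(float)
        present = n_i > 0
        r = int(present.sum())
        if r < 2:
            continue
        uniq = np.unique(np.concatenate([v1, v2]))
        if uniq.size < 2:
            continue
        nbar = n_i[present].mean()
        if nbar <= 1:
            continue
        sum_n2 = float((n_i[present] ** 2).sum())
        nc = (r * nbar - sum_n2 / (r * nbar)) / (r - 1)
        for u in uniq:
            c1 = (v1 == u)
            c2 = (v2 == u)
            copies = c1.astype(int) + c2.astype(int)
            cnt = np.bincount(pv, weights=copies, minlength=n_pops)
            het = np.bincount(pv, weights=(copies == 1), minlength=n_pops)
            p_i = np.zeros(n_pops)
            h_i = np.zeros(n_pops)
            p_i[present] = cnt[present] / (2 * n_i[present])
            h_i[present] = het[present] / n_i[present]
            pbar = float((n_i * p_i).sum() / (r * nbar))
            s2 = float((n_i[present] * (p_i[present] - pbar) ** 2).sum() / ((r - 1) * nbar))
            hbar = float((n_i * h_i).sum() / (r * nbar))
            inner = pbar * (1 - pbar) - (r - 1) / r * s2
            a_comp = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
            b_comp = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            c_comp = hbar / 2
            sums_a[l] += a_comp
            sums_abc[l] += a_comp + b_comp + c_comp
    return sums_a, sums_abc


@dataclass
class FstResult:
    theta_global: float
    per_locus_theta: dict[str, float]
    pairwise: pd.DataFrame | None = None
    pairwise_p: pd.DataFrame | None = None
    pairwise_p_by: pd.DataFrame | None = None
    permutations: int = 0
    seed: int | None = None

    def summary(self) -> str:
        lines = [f"Weir-Cockerham theta (global): {self.theta_global:.4f}"]
        if self.pairwise is not None:
            lines.append("pairwise theta:\n" + self.pairwise.round(4).to_string())
            lines.append("permutation p (BY-adjusted):\n"
                         + self.pairwise_p_by.round(4).to_string())
        return "\n".join(lines)


def wc_theta(
    dataset: GenotypeDataset | tuple[np.ndarray, np.ndarray],
    n_pops: int | None = None,
) -> FstResult:
    """Global and per-locus Weir-Cockerham theta (ratio of sums).

    Accepts either a :class:`GenotypeDataset` or a pre-flattened
    ``(alleles, pops)`` array pair.  Requires at least two populations with
    data and at least one polymorphic locus.
    """
    if isinstance(dataset, GenotypeDataset):
        alleles, pops = dataset_arrays(dataset)
        n_pops = dataset.n_pops
        locus_names = dataset.locus_names
    else:
        alleles, pops = dataset
        if n_pops is None:
            n_pops = int(pops.max()) + 1
        locus_names = [f"locus{l + 1}" for l in range(alleles.shape[1])]
    if n_pops < 2:
        raise ValueError("need at least 2 populations")
    sums_a, sums_abc = _theta_sums(alleles, pops, n_pops)
    total_abc = sums_abc.sum()
    if total_abc == 0:
        raise ValueError("all loci monomorphic; theta undefined")
    per_locus = {
        name: (sums_a[l] / sums_abc[l] if sums_abc[l] != 0 else float("nan"))
        for l, name in enumerate(locus_names)
    }
    return FstResult(
        theta_global=float(sums_a.sum() / total_abc), per_locus_theta=per_locus
    )


def pairwise_fst(
    dataset: GenotypeDataset,
    permutations: int = 1000,
    seed: int | None = None,
) -> FstResult:
    """Pairwise theta with permutation p-values and BY-FDR across pairs.

    Significance permutes whole individuals (multilocus genotypes) between
    the two populations of a pair; ``p = (1 + #{theta_perm >= theta_obs}) /
    (permutations + 1)``.
    """
    alleles, pops = dataset_arrays(dataset)
    n_pops = dataset.n_pops
    names = dataset.pop_names
    theta = np.full((n_pops, n_pops), np.nan)
    pvals = np.full((n_pops, n_pops), np.nan)
    rng = np.random.default_rng(seed)
    flat_p = []
    pair_order = []
    for i in range(n_pops):
        for j in range(i + 1, n_pops):
            sel = (pops == i) | (pops == j)
            sub_alleles = alleles[sel]
            sub_pops = (pops[sel] == j).astype(np.int64)
            t_obs = _pair_theta(sub_alleles, sub_pops)
            hits = 0
            labels = sub_pops.copy()
            for _ in range(permutations):
                rng.shuffle(labels)
                if _pair_theta(sub_alleles, labels) >= t_obs - 1e-12:
                    hits += 1
            p = (1 + hits) / (1 + permutations)
            theta[i, j] = theta[j, i] = t_obs
            pvals[i, j] = pvals[j, i] = p
            flat_p.append(p)
            pair_order.append((i, j))
    adj = by_fdr(flat_p)
    p_by = np.full((n_pops, n_pops), np.nan)
    for (i, j), q in zip(pair_order, adj):
        p_by[i, j] = p_by[j, i] = q
    global_res = wc_theta(dataset)
    return FstResult(
        theta_global=global_res.theta_global,
        per_locus_theta=global_res.per_locus_theta,
        pairwise=pd.DataFrame(theta, index=names, columns=names),
        pairwise_p=pd.DataFrame(pvals, index=names, columns=names),
        pairwise_p_by=pd.DataFrame(p_by, index=names, columns=names),
        permutations=permutations,
        seed=seed,
    )


def _pair_theta(alleles: np.ndarray, pops01: np.ndarray) -> float:
    sums_a, sums_abc = _theta_sums(alleles, pops01, 2)
    total = sums_abc.sum()
    if total == 0:
        return 0.0
    return float(sums_a.sum() / total)


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaLevel:
    df: int
    ssd: float
    sigma2: float
    percent: float


@dataclass
class AmovaResult:
    levels: dict[str, AmovaLevel]
    phi_st: float
    phi_sc: float | None
    phi_ct: float | None
    p_values: dict[str, float]
    permutations: int
    seed: int | None
    negative_components: bool = False

    def summary(self) -> str:
        rows = []
        for name, lv in self.levels.items():
            rows.append(
                f"{name:<32s} df={lv.df:<5d} SSD={lv.ssd:9.3f} "
                f"sigma2={lv.sigma2:8.4f} %={lv.percent:6.2f}"
            )
        phi = [f"Phi_ST={self.phi_st:.4f}"]
        if self.phi_sc is not None:
            phi.append(f"Phi_SC={self.phi_sc:.4f}")
        if self.phi_ct is not None:
            phi.append(f"Phi_CT={self.phi_ct:.4f}")
        rows.append("  ".join(phi))
        rows.append("p: " + ", ".join(f"{k}={v:.4f}" for k, v in self.p_values.items()))
        return "\n".join(rows)


def _gene_matrix(alleles: np.ndarray, pops: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split individuals into gene copies: (2N, L) allele codes, (2N,) pops."""
    n, L, _ = alleles.shape
    genes = alleles.transpose(0, 2, 1).reshape(2 * n, L)
    gpops = np.repeat(pops, 2)
    return genes, gpops


def _ss_within(genes: np.ndarray, member: np.ndarray) -> float:
    """Sum over loci of SS for the gene copies in ``member``.

    With 0/1 distances, ``SS = (n^2 - sum_u c_u^2) / (2n)`` per locus, where
    ``c_u`` are allele counts among the n non-missing copies.
    """
    total = 0.0
    sub = genes[member]
    for l in range(genes.shape[1]):
        col = sub[:, l]
        col = col[col >= 0]
        n = col.size
        if n < 2:
            continue
        _, counts = np.unique(col, return_counts=True)
        total += (n * n - float((counts**2).sum())) / (2 * n)
    return total


def _amova_components(
    genes: np.ndarray, gpops: np.ndarray, pop_group: np.ndarray
) -> tuple[dict[str, float], dict[str, int]]:
    """SSDs, dfs and variance components for one grouping arrangement."""
    n_pops = int(pop_group.size)
    groups = np.unique(pop_group)
    G = groups.size
    valid_any = (genes >= 0).any(axis=1)
    n_genes = int(valid_any.sum())

    ss_pop = 0.0
    for p in range(n_pops):
        ss_pop += _ss_within(genes, gpops == p)
    ss_group = 0.0
    for g in groups:
        member_pops = np.where(pop_group == g)[0]
        ss_group += _ss_within(genes, np.isin(gpops, member_pops))
    ss_total = _ss_within(genes, np.ones(genes.shape[0], dtype=bool))

    ssd_wp = ss_pop
    ssd_ap = ss_group - ss_pop
    ssd_ag = ss_total - ss_group

    # gene counts per pop/group (copies with data at >= 1 locus)
    n_p = np.array([int(((gpops == p) & valid_any).sum()) for p in range(n_pops)])
    n = int(n_p.sum())
    df_wp = n - n_pops
    df_ap = n_pops - G
    df_ag = G - 1

    sizes = {"n_p": n_p, "n": n}
    out = {
        "ssd_wp": ssd_wp, "ssd_ap": ssd_ap, "ssd_ag": ssd_ag,
    }
    dfs = {"df_wp": df_wp, "df_ap": df_ap, "df_ag": df_ag}

    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
    if G > 1:
        per_group_sq = []
        n_g = []
        for g in groups:
            member = pop_group == g
            ng = n_p[member].sum()
            n_g.append(ng)
            per_group_sq.append((n_p[member] ** 2).sum() / ng if ng else 0.0)
        sum_gsq = float(np.sum(per_group_sq))
        n_g = np.array(n_g, dtype=float)
        n1 = (n - sum_gsq) / df_ap if df_ap > 0 else float("nan")
        n2 = (sum_gsq - (n_p**2).sum() / n) / df_ag
        n3 = (n - (n_g**2).sum() / n) / df_ag
        ms_ap = ssd_ap / df_ap if df_ap > 0 else 0.0
        ms_ag = ssd_ag / df_ag
        sigma_b = (ms_ap - sigma_c) / n1 if df_ap > 0 else 0.0
        sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
        out.update(sigma_a=sigma_a, sigma_b=sigma_b, sigma_c=sigma_c)
    else:
        n1 = (n - (n_p**2).sum() / n) / df_ap if df_ap > 0 else float("nan")
        ms_ap = ssd_ap / df_ap if df_ap > 0 else 0.0
        sigma_b = (ms_ap - sigma_c) / n1 if df_ap > 0 else 0.0
        out.update(sigma_a=0.0, sigma_b=sigma_b, sigma_c=sigma_c)
    return out | dfs, sizes


def amova(
    dataset: GenotypeDataset,
    grouping: dict[str, str] | None = None,
    permutations: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA on 0/1 allele-identity distances.

    ``grouping`` maps population name to group id (defaults to the dataset's
    ``group_ids``); with a single group the among-group level is absent and a
    two-level AMOVA is returned.  Negative variance components are reported
    as computed, clamped to zero only for the percentage display, and
    flagged.  Permutation schemes: Phi_ST permutes gene copies among all
    populations; Phi_SC permutes gene copies among populations within groups;
    Phi_CT permutes whole populations among groups.
    """
    if dataset.n_pops < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    if grouping is None:
        gids = dataset.group_ids or ["group1"] * dataset.n_pops
        grouping = dict(zip(dataset.pop_names, gids))
    missing = set(dataset.pop_names) - set(grouping)
    if missing:
        raise ValueError(f"grouping does not cover populations: {sorted(missing)}")
    pop_group_labels = [grouping[p] for p in dataset.pop_names]
    label_to_int = {g: i for i, g in enumerate(dict.fromkeys(pop_group_labels))}
    pop_group = np.array([label_to_int[g] for g in pop_group_labels])

    alleles, pops = dataset_arrays(dataset)
    genes, gpops = _gene_matrix(alleles, pops)
    comp, _ = _amova_components(genes, gpops, pop_group)
    G = len(label_to_int)

    sa, sb, sc = comp["sigma_a"], comp["sigma_b"], comp["sigma_c"]
    total = sa + sb + sc
    negative = sa < 0 or sb < 0 or sc < 0
    clamp = np.clip([sa, sb, sc], 0, None)
    pct_total = clamp.sum()
    pct = 100 * clamp / pct_total if pct_total > 0 else np.zeros(3)

    phi_st = (sa + sb) / total if total != 0 else float("nan")
    phi_sc = sb / (sb + sc) if G > 1 and (sb + sc) != 0 else (None if G == 1 else float("nan"))
    phi_ct = sa / total if G > 1 and total != 0 else (None if G == 1 else float("nan"))
    if G == 1:
        phi_st = sb / total if total != 0 else float("nan")

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}

    def perm_p(stat_obs: float, stat_fn, scheme: str) -> float:
        hits = 0
        for _ in range(permutations):
            if scheme == "genes_all":
                perm = rng.permutation(gpops)
                c, _ = _amova_components(genes, perm, pop_group)
            elif scheme == "genes_within_groups":
                perm = gpops.copy()
                for g in range(G):
                    member_pops = np.where(pop_group == g)[0]
                    sel = np.isin(gpops, member_pops)
                    perm[sel] = rng.permutation(gpops[sel])
                c, _ = _amova_components(genes, perm, pop_group)
            else:  # pops among groups
                c, _ = _amova_components(genes, gpops, rng.permutation(pop_group))
            if stat_fn(c) >= stat_obs - 1e-12:
                hits += 1
        return (1 + hits) / (1 + permutations)

    if permutations > 0:
        if G > 1:
            tot = lambda c: c["sigma_a"] + c["sigma_b"] + c["sigma_c"]
            p_values["phi_st"] = perm_p(
                phi_st, lambda c: (c["sigma_a"] + c["sigma_b"]) / tot(c) if tot(c) else 0.0,
                "genes_all")
            p_values["phi_sc"] = perm_p(
                phi_sc,
                lambda c: c["sigma_b"] / (c["sigma_b"] + c["sigma_c"])
                if (c["sigma_b"] + c["sigma_c"]) else 0.0,
                "genes_within_groups")
            p_values["phi_ct"] = perm_p(
                phi_ct, lambda c: c["sigma_a"] / tot(c) if tot(c) else 0.0,
                "pops_among_groups")
        else:
            tot = lambda c: c["sigma_b"] + c["sigma_c"]
            p_values["phi_st"] = perm_p(
                phi_st, lambda c: c["sigma_b"] / tot(c) if tot(c) else 0.0,
                "genes_all")

    levels: dict[str, AmovaLevel] = {}
    if G > 1:
        levels["among_groups"] = AmovaLevel(comp["df_ag"], comp["ssd_ag"], sa, float(pct[0]))
        levels["among_pops_within_groups"] = AmovaLevel(comp["df_ap"], comp["ssd_ap"], sb, float(pct[1]))
        levels["within_pops"] = AmovaLevel(comp["df_wp"], comp["ssd_wp"], sc, float(pct[2]))
    else:
        pct2_total = max(clamp[1] + clamp[2], 0)
        pct_ap = 100 * clamp[1] / pct2_total if pct2_total > 0 else 0.0
        levels["among_pops"] = AmovaLevel(comp["df_ap"], comp["ssd_ap"], sb, float(pct_ap))
        levels["within_pops"] = AmovaLevel(comp["df_wp"], comp["ssd_wp"], sc, float(100 - pct_ap if pct2_total > 0 else 0.0))
    return AmovaResult(
        levels=levels,
        phi_st=float(phi_st),
        phi_sc=None if phi_sc is None else float(phi_sc),
        phi_ct=None if phi_ct is None else float(phi_ct),
        p_values=p_values,
        permutations=permutations,
        seed=seed,
        negative_components=bool(negative),
    )


# ---------------------------------------------------------------------------
# admixture model (STRUCTURE-style Gibbs sampler)


@dataclass
class StructureResult:
    """Posterior summaries from one admixture-model chain."""

    k: int
    q_matrix: np.ndarray  # individuals x K, label-matched posterior mean
    ln_p_data: float
    lnl_trace: np.ndarray
    burnin: int
    reps: int
    seed: int | None

    def summary(self) -> str:
        mean_max_q = float(self.q_matrix.max(axis=1).mean())
        return (
            f"K={self.k}  ln P(D)={self.ln_p_data:.2f}  "
            f"mean max q={mean_max_q:.3f}  (burnin={self.burnin}, reps={self.reps})"
        )


class AdmixtureModel:
    """Bayesian admixture clustering of multilocus genotypes.

    Each allele copy carries a latent cluster of origin ``z``; a Gibbs sweep
    updates (i) per-cluster allele frequencies ~ Dirichlet(lambda + counts),
    (ii) per-individual admixture ~ Dirichlet(alpha + origin counts), and
    (iii) the origins ``z`` ~ categorical proportional to ``q_k * p_k``.
    ``alpha`` is held fixed (no ancestry-prior updating) and allele
    frequencies are independent across clusters.  Missing alleles are
    skipped.  ``ln P(D)`` is estimated as ``mean(lnL) - var(lnL)/2`` over
    post-burnin sweeps.
    """

    def __init__(self, dataset: GenotypeDataset, k: int,
                 alpha: float = 1.0, lam: float = 1.0):
        if k < 1:
            raise ValueError("K must be >= 1")
        if dataset.n_individuals == 0:
            raise ValueError("empty dataset")
        self.k = k
        self.alpha = alpha
        self.lam = lam
        alleles, pops = dataset_arrays(dataset)
        self.n_ind, self.n_loci, _ = alleles.shape
        self.pops = pops
        # recode alleles per locus to 0..k_l-1
        self.n_alleles = np.zeros(self.n_loci, dtype=int)
        coded = np.full_like(alleles, -1)
        for l in range(self.n_loci):
            col = alleles[:, l, :]
            uniq = np.unique(col[col >= 0])
            self.n_alleles[l] = uniq.size
            lookup = {a: i for i, a in enumerate(uniq)}
            for c in range(2):
                coded[:, l, c] = [lookup.get(a, -1) for a in col[:, c]]
        ind_idx, locus_idx, copy_idx = np.nonzero(coded >= 0)
        self.ind_idx = ind_idx
        self.locus_idx = locus_idx
        self.allele_code = coded[ind_idx, locus_idx, copy_idx]
        self.a_max = int(self.n_alleles.max())
        self.valid_mask = np.zeros((self.n_loci, self.a_max))
        for l in range(self.n_loci):
            self.valid_mask[l, : self.n_alleles[l]] = 1.0

    def fit(self, burnin: int = 2000, reps: int = 10000,
            seed: int | None = None) -> StructureResult:
        """Run one chain of ``reps`` sweeps, discarding ``burnin``."""
        if reps <= 0:
            raise ValueError("reps must be positive")
        rng = np.random.default_rng(seed)
        K, C = self.k, self.ind_idx.size
        z = rng.integers(0, K, size=C)
        lnl_trace = np.empty(reps)
        q_samples = []
        ref_q = None
        keep = burnin < reps
        for sweep in range(reps):
            # (i) allele frequencies per cluster
            counts_p = np.zeros((K, self.n_loci, self.a_max))
            np.add.at(counts_p, (z, self.locus_idx, self.allele_code), 1.0)
            gam = rng.standard_gamma(self.lam + counts_p) * self.valid_mask[None]
            p = gam / gam.sum(axis=2, keepdims=True)
            # (ii) admixture proportions per individual
            counts_q = np.zeros((self.n_ind, K))
            np.add.at(counts_q, (self.ind_idx, z), 1.0)
            gq = rng.standard_gamma(self.alpha + counts_q)
            q = gq / gq.sum(axis=1, keepdims=True)
            # (iii) origins
            w = q[self.ind_idx] * p[:, self.locus_idx, self.allele_code].T  # (C, K)
            tot = w.sum(axis=1)
            lnl_trace[sweep] = float(np.log(tot).sum())
            if K > 1:
                cum = np.cumsum(w, axis=1)
                u = rng.random(C) * tot
                z = (cum < u[:, None]).sum(axis=1)
                np.clip(z, 0, K - 1, out=z)
            if keep and sweep >= burnin:
                if ref_q is None:
                    ref_q = q
                    perm = np.arange(K)
                else:
                    perm = _match_labels(ref_q, q)
                q_samples.append(q[:, perm])
        post = lnl_trace[burnin:] if keep else lnl_trace
        ln_p = float(post.mean() - post.var() / 2.0)
        q_mean = np.mean(q_samples, axis=0) if q_samples else np.full((self.n_ind, K), 1.0 / K)
        q_mean = q_mean / q_mean.sum(axis=1, keepdims=True)
        return StructureResult(
            k=K, q_matrix=q_mean, ln_p_data=ln_p, lnl_trace=lnl_trace,
            burnin=burnin, reps=reps, seed=seed,
        )


def _match_labels(ref_q: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Greedy column matching of ``q`` onto ``ref_q`` (label switching)."""
    k = ref_q.shape[1]
    cost = ref_q.T @ q  # (K_ref, K)
    perm = np.full(k, -1)
    used_ref = set()
    used = set()
    for _ in range(k):
        best = None
        for i in range(k):
            if i in used_ref:
                continue
            for j in range(k):
                if j in used:
                    continue
                if best is None or cost[i, j] > cost[best[0], best[1]]:
                    best = (i, j)
        perm[best[0]] = best[1]
        used_ref.add(best[0])
        used.add(best[1])
    return perm


def structure_fit(
    dataset: GenotypeDataset,
    k: int,
    burnin: int = 2000,
    reps: int = 10000,
    alpha: float = 1.0,
    lam: float = 1.0,
    seed: int | None = None,
) -> StructureResult:
    """Convenience wrapper: build an :class:`AdmixtureModel` and fit it."""
    return AdmixtureModel(dataset, k, alpha=alpha, lam=lam).fit(
        burnin=burnin, reps=reps, seed=seed
    )


def select_k(results: list[StructureResult]) -> tuple[int, pd.DataFrame]:
    """Parsimonious K: smallest K within 2 ln-units of the best ln P(D).

    Returns the chosen K and the full ln P(D) table (mean over replicate
    chains per K when several are supplied).
    """
    if not results:
        raise ValueError("no results")
    table = (
        pd.DataFrame(
            {"K": [r.k for r in results], "ln_p_data": [r.ln_p_data for r in results]}
        )
        .groupby("K", as_index=False)
        .mean()
        .sort_values("K", ignore_index=True)
    )
    best = table["ln_p_data"].max()
    eligible = table[table["ln_p_data"] >= best - 2.0]
    return int(eligible["K"].min()), table
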