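"""TF-phenotype association discovery by hypergeometric enrichment.

The statistical engine asks, for each (TF, drug) pair, whether the TF's
"binding-change SNPs" (the top-ranked variants by predicted binding impact
among SNPs inside the TF's ChIP peaks) overlap the drug's
"phenotype-associated SNPs" (cis-eQTLs of genes whose expression correlates
with the drug's EC50, restricted to each gene's Hi-C-derived regulatory
region) more than chance would allow within a universe of accessible SNPs.
Enrichment is a hypergeometric upper-tail test, corrected across all pairs
by Benjamini-Hochberg FDR.  A randomized control — size-matched SNP subsets
drawn from within the TF's peaks — yields an empirical "utility p score"
measuring how much the impact predictor itself (rather than mere peak
membership) contributes to the observed enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import CohortData, GenomicInterval, LoopPair, SnpRecord, snp_in_interval

EQTL_ALPHA = 0.05       # strict: p < 0.05 declares a cis-eQTL
DRUG_GENE_ALPHA = 0.05  # inclusive: p <= 0.05 declares a drug-response gene
TOP_K_DEFAULT = 300
UTILITY_REPS_DEFAULT = 100
FDR_ALPHA = 0.05


@dataclass(frozen=True)
class AssociationResult:
    """One TF-drug enrichment test."""

    tf: str
    drug: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    q_value: float | None = None
    utility_p: float | None = None


@dataclass(frozen=True)
class EqtlResult:
    slope: float
    p_value: float
    n: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Regulatory regions from Hi-C domains and loops
# ---------------------------------------------------------------------------


def regulatory_region(
    gene_interval: GenomicInterval,
    domains: Sequence[GenomicInterval],
    loops: Sequence[LoopPair],
) -> list[GenomicInterval]:
    """Cis-regulatory region of a gene: every chromatin domain the gene
    overlaps, plus — for each loop touching the gene — the partner anchor
    (both anchors when both touch the gene).  May be empty."""
    region = [d for d in domains if d.overlaps(gene_interval)]
    for loop in loops:
        o1 = loop.anchor1.overlaps(gene_interval)
        o2 = loop.anchor2.overlaps(gene_interval)
        if o1 and o2:
            region.extend([loop.anchor1, loop.anchor2])
        elif o1:
            region.append(loop.anchor2)
        elif o2:
            region.append(loop.anchor1)
    return region


# ---------------------------------------------------------------------------
# eQTL and drug-response-gene tests
# ---------------------------------------------------------------------------


def eqtl_test(dosages: Sequence[float], expression: Sequence[float]) -> EqtlResult:
    """Additive-model eQTL test: simple linear regression of expression on
    minor-allele dosage, two-sided t-test on the slope (df = m - 2 over the
    m complete pairs).  Missing values are dropped pairwise."""
    d = np.asarray(dosages, dtype=float)
    e = np.asarray(expression, dtype=float)
    keep = ~(np.isnan(d) | np.isnan(e))
    d, e = d[keep], e[keep]
    if d.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {d.size}")
    if np.ptp(d) == 0:
        return EqtlResult(slope=0.0, p_value=1.0, n=int(d.size), degenerate=True)
    fit = stats.linregress(d, e)
    p = float(fit.pvalue) if np.isfinite(fit.pvalue) else 1.0
    return EqtlResult(slope=float(fit.slope), p_value=p, n=int(d.size))


def drug_response_genes(
    expression: pd.DataFrame,
    ec50: pd.Series,
    alpha: float = DRUG_GENE_ALPHA,
) -> list[str]:
    """Genes whose expression correlates with EC50 at p <= alpha (two-sided
    Pearson t-test).  Constant expression rows are excluded."""
    genes: list[str] = []
    y_all = ec50.to_numpy(dtype=float)
    for gene, row in expression.iterrows():
        x = row.to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y_all))
        if keep.sum() < 3:
            continue
        xs, ys = x[keep], y_all[keep]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            continue
        r, p = stats.pearsonr(xs, ys)
        if p <= alpha:
            genes.append(str(gene))
    return genes


def phenotype_associated_snps(
    ec50: pd.Series,
    cohort: CohortData,
    genes: Mapping[str, GenomicInterval],
    regions: Mapping[str, Sequence[GenomicInterval]],
    snps: Sequence[SnpRecord],
    alpha_gene: float = DRUG_GENE_ALPHA,
    alpha_eqtl: float = EQTL_ALPHA,
    eqtl_cache: dict | None = None,
) -> frozenset[str]:
    """Union over the drug's response genes of in-region SNPs that are
    cis-eQTLs (p < alpha_eqtl) of the gene."""
    drgs = [g for g in drug_response_genes(cohort.expression, ec50, alpha_gene)
            if g in genes]
    out: set[str] = set()
    for gene in drgs:
        region = regions.get(gene, ())
        for snp in snps:
            if not any(snp_in_interval(snp, iv) for iv in region):
                continue
            if snp.snp_id not in cohort.genotypes.index:
                continue
            key = (snp.snp_id, gene)
            if eqtl_cache is not None and key in eqtl_cache:
                p = eqtl_cache[key]
            else:
                res = eqtl_test(
                    cohort.genotypes.loc[snp.snp_id].to_numpy(dtype=float),
                    cohort.expression.loc[gene].to_numpy(dtype=float),
                )
                p = res.p_value
                if eqtl_cache is not None:
                    eqtl_cache[key] = p
            if p < alpha_eqtl:
                out.add(snp.snp_id)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Binding-change SNPs
# ---------------------------------------------------------------------------


def binding_change_snps(
    peak_snps: Iterable[str],
    delta_a: Mapping[str, float],
    delta_b: Mapping[str, float] | None = None,
    top_k: int = TOP_K_DEFAULT,
) -> frozenset[str]:
    """SNPs inside the TF's peaks ranked in the top ``top_k`` by either
    impact scorer (union).  A missing score ranks last (-inf); exact score
    ties break lexicographically by snp_id.  If the peak pool is no larger
    than ``top_k``, every peak SNP qualifies."""
    pool = sorted(set(peak_snps))
    if not pool:
        return frozenset()
    if len(pool) <= top_k:
        return frozenset(pool)
    out: set[str] = set()
    for scorer in (delta_a, delta_b):
        if scorer is None:
            continue
        ranked = sorted(pool, key=lambda s: (-scorer.get(s, float("-inf")), s))
        out.update(ranked[:top_k])
    return frozenset(out)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment, FDR, randomized controls
# ---------------------------------------------------------------------------


def hypergeom_enrichment(
    universe: Iterable[str], set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[int, int, int, int, float]:
    """Upper-tail hypergeometric test of the overlap of two SNP sets.

    Both sets are intersected with the universe first.  Returns
    (N, K, n, k, p) with p = P(X >= k), X ~ Hypergeometric(N, K, n),
    evaluated in log space by scipy.
    """
    U = frozenset(universe)
    if not U:
        raise ValueError("empty universe")
    A = frozenset(set_a) & U
    B = frozenset(set_b) & U
    N, K, n, k = len(U), len(A), len(B), len(A & B)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return N, K, n, k, min(max(p, 0.0), 1.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bh_nominal_cutoff(
    n_discoveries: int, n_tests: int, alpha: float = FDR_ALPHA
) -> float:
    """The per-test nominal p threshold implied by a BH step-up outcome:
    with j discoveries among m tests at FDR alpha, every rejected test has
    p <= alpha * j / m."""
    if not (0 <= n_discoveries <= n_tests) or n_tests < 1:
        raise ValueError("need 0 <= discoveries <= tests, tests >= 1")
    return alpha * n_discoveries / n_tests


def impact_utility_pscore(
    peak_snps: Iterable[str],
    set_size: int,
    pheno_snps: Iterable[str],
    universe: Iterable[str],
    observed_p: float,
    n_reps: int = UTILITY_REPS_DEFAULT,
    seed: int = 0,
) -> float:
    """Fraction of size-matched random within-peak SNP subsets whose
    enrichment p is strictly smaller than the observed one.

    A low score means the impact predictor, not peak membership alone,
    drives the association.
    """
    pool = sorted(set(peak_snps))
    if len(pool) < set_size:
        raise ValueError(
            f"peak pool ({len(pool)}) smaller than binding-change set ({set_size})"
        )
    pheno = frozenset(pheno_snps)
    U = frozenset(universe)
    rng = np.random.default_rng(seed)
    smaller = 0
    for _ in range(n_reps):
        idx = rng.choice(len(pool), size=set_size, replace=False)
        control = (pool[i] for i in idx)
        _, _, _, _, p = hypergeom_enrichment(U, pheno, control)
        if p < observed_p:
            smaller += 1
    return smaller / n_reps


# ---------------------------------------------------------------------------
# The full panel
# ---------------------------------------------------------------------------


def run_all_pairs(
    binding_sets: Mapping[str, frozenset[str]],
    pheno_sets: Mapping[str, frozenset[str]],
    universe: Iterable[str],
    utility_pools: Mapping[str, Iterable[str]] | None = None,
    n_utility_reps: int = UTILITY_REPS_DEFAULT,
    seed: int = 0,
) -> list[AssociationResult]:
    """One hypergeometric test per (TF, drug); BH correction across all
    pairs jointly; results sorted by p (ties by TF then drug name).

    When ``utility_pools`` maps TFs to their within-peak SNP pools, the
    randomized-control utility p score is computed for every pair.
    """
    U = frozenset(universe)
    results: list[AssociationResult] = []
    seq = 0
    for tf in sorted(binding_sets):
        for drug in sorted(pheno_sets):
            N, K, n, k, p = hypergeom_enrichment(U, pheno_sets[drug], binding_sets[tf])
            utility = None
            if utility_pools is not None and n > 0:
                utility = impact_utility_pscore(
                    utility_pools[tf],
                    set_size=len(frozenset(binding_sets[tf]) & U),
                    pheno_snps=pheno_sets[drug],
                    universe=U,
                    observed_p=p,
                    n_reps=n_utility_reps,
                    seed=seed + seq,
                )
            results.append(
                AssociationResult(tf=tf, drug=drug, N=N, K=K, n=n, k=k,
                                  p_value=p, utility_p=utility)
            )
            seq += 1
    qs = bh_fdr([r.p_value for r in results])
    results = [replace(r, q_value=float(q)) for r, q in zip(results, qs)]
    results.sort(key=lambda r: (r.p_value, r.tf, r.drug))
    return results


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tf": r.tf, "drug": r.drug, "N": r.N, "K": r.K, "n": r.n,
                "k": r.k, "p_value": r.p_value, "q_value": r.q_value,
                "utility_p": r.utility_p,
            }
            for r in results
        ]
    )
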