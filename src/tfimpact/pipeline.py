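"""End-to-end orchestration: from study inputs to TF-drug associations.

This is thin glue over the component modules: it scores every within-peak
SNP with a binding predictor, ranks binding-change SNPs, builds each drug's
phenotype-associated SNP set, and runs the hypergeometric panel with
randomized-control utility scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import association
from .association import AssociationResult, regulatory_region, run_all_pairs
from .formats_io import GenomicInterval, SnpRecord, snp_in_interval
from .stap import CalibratedStap, LinearCalibration, OccupancyModel
from .synthetic import Study
from .variant import delta_score

DEFAULT_TAU = 2.0
DEFAULT_ET = 3.0


def snps_in_intervals(
    snps: Sequence[SnpRecord], intervals: Sequence[GenomicInterval]
) -> list[SnpRecord]:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    return [
        s
        for s in snps
        if any(snp_in_interval(s, iv) for iv in by_chrom.get(s.chrom, ()))
    ]


def peak_snp_deltas(
    study: Study,
    tf: str,
    predictor=None,
    tau: float = DEFAULT_TAU,
    eT: float = DEFAULT_ET,
) -> dict[str, float]:
    """Impact score of every SNP inside the TF's peaks.

    The default predictor is the TF's occupancy model at fixed (tau, eT)
    with an identity calibration — rankings, and hence binding-change sets,
    are invariant under the linear calibration.
    """
    if predictor is None:
        predictor = CalibratedStap(
            model=OccupancyModel(study.pwms[tf], tau=tau, eT=eT),
            calibration=LinearCalibration.identity(),
        )
    out: dict[str, float] = {}
    for snp in snps_in_intervals(study.snps, study.peaks[tf]):
        out[snp.snp_id] = delta_score(snp, study.genome, predictor)
    return out


def gene_regulatory_regions(study: Study) -> dict[str, list[GenomicInterval]]:
    return {
        gene: regulatory_region(iv, study.domains, study.loops)
        for gene, iv in study.genes.items()
    }


@dataclass
class StudyRun:
    """Everything the association panel computed on one study."""

    results: list[AssociationResult]
    binding_sets: dict[str, frozenset[str]]
    pheno_sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    peak_pools: dict[str, list[str]]


def run_study(
    study: Study,
    top_k: int | None = None,
    tau: float = DEFAULT_TAU,
    eT: float = DEFAULT_ET,
    n_utility_reps: int = association.UTILITY_REPS_DEFAULT,
    compute_utility: bool = True,
    seed: int = 0,
) -> StudyRun:
    """Run the full association pipeline on a (synthetic or loaded) study."""
    if top_k is None:
        top_k = int(study.truth.get("top_k", association.TOP_K_DEFAULT))
    universe = frozenset(
        s.snp_id for s in snps_in_intervals(study.snps, study.dhs)
    )

    peak_pools: dict[str, list[str]] = {}
    binding_sets: dict[str, frozenset[str]] = {}
    for tf in study.peaks:
        deltas = peak_snp_deltas(study, tf, tau=tau, eT=eT)
        peak_pools[tf] = sorted(deltas)
        binding_sets[tf] = association.binding_change_snps(
            peak_pools[tf], deltas, top_k=top_k
        )

    regions = gene_regulatory_regions(study)
    eqtl_cache: dict = {}
    pheno_sets = {
        drug: association.phenotype_associated_snps(
            study.cohort.phenotypes.loc[drug],
            study.cohort,
            study.genes,
            regions,
            study.snps,
            eqtl_cache=eqtl_cache,
        )
        for drug in study.drugs
    }

    results = run_all_pairs(
        binding_sets,
        pheno_sets,
        universe,
        utility_pools=peak_pools if compute_utility else None,
        n_utility_reps=n_utility_reps,
        seed=seed,
    )
    return StudyRun(
        results=results,
        binding_sets=binding_sets,
        pheno_sets=pheno_sets,
        universe=universe,
        peak_pools=peak_pools,
    )
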