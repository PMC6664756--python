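"""Synthetic fixtures with planted ground truth for every pipeline input.

Three generators cover the pipeline's needs without any external data:

* :func:`gen_genome` — i.i.d. background sequence at a chosen GC content.
* :func:`gen_chip_windows` — labeled ChIP-like training windows whose signal
  is analytic occupancy under a known (tau, eT) plus Gaussian noise, with
  planted motif sites recorded in a truth sidecar.
* :func:`simulate_study` — a complete cohort study emulating the causal
  chain SNP -> TF binding -> gene expression -> drug response (EC50):
  a genome with planted TF sites inside ChIP peaks, site-destroying SNPs
  wired through additive eQTL effects into the expression of designated
  genes, whose expression in turn drives one drug's EC50; Hi-C domains and
  one loop define each gene's regulatory region, and DNase-accessible
  intervals cover all SNPs (the test universe).

Every recovery test reads planted truth only from the returned truth
mapping (or its JSON sidecar on disk), never from generator internals.
Genotypes are Hardy-Weinberg binomial draws with no linkage disequilibrium;
see docs/methods.md for what this does and does not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    BASES,
    CohortData,
    GenomicInterval,
    LoopPair,
    Pwm,
    SnpRecord,
    write_fasta,
    write_intervals,
    write_matrix,
    write_pwm_set,
    write_snp_table,
)
from .stap import LabeledWindow, OccupancyModel

# -- tiny-preset study conditions (scaled-down analogue of a 284-sample,
#    24-drug, 37-TF cohort; rationale in docs/methods.md) --------------------
TINY = {
    "chrom": "chr1",
    "length": 400_000,
    "gc": 0.41,
    "domain_size": 20_000,
    "n_samples": 120,
    "tfs": ("TF_A", "TF_B"),
    "drugs": ("drugA", "drugB", "drugC"),
    "causal_tf": "TF_A",
    "causal_drug": "drugA",
    "n_causal_genes": 10,
    "motif_width": 8,
    "consensus_prob": 0.85,
    "peak_half_width": 150,
    "beta_eqtl": 0.8,     # expression slope per causal-SNP dosage
    "beta_pheno": 0.4,    # EC50 loading per causal gene
    "causal_maf": 0.3,
    "top_k": 40,
}


def gen_genome(
    n_chroms: int = 1,
    length: int = 100_000,
    gc: float = 0.41,
    seed: int = 0,
) -> dict[str, str]:
    """i.i.d. random genome with P(G) + P(C) = gc."""
    if not (0.0 < gc < 1.0):
        raise ValueError(f"gc must lie strictly inside (0, 1), got {gc}")
    if length < 1000:
        raise ValueError("chromosomes shorter than 1 kb are not useful fixtures")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"chr{i + 1}": "".join(
            np.array(list(BASES))[rng.choice(4, size=length, p=probs)]
        )
        for i in range(n_chroms)
    }


def random_pwm(
    width: int = 8,
    consensus_prob: float = 0.85,
    seed: int = 0,
    name: str = "motif",
) -> Pwm:
    """A sharp random motif: one preferred base per position."""
    rng = np.random.default_rng(seed)
    probs = np.full((width, 4), (1.0 - consensus_prob) / 3)
    for j, b in enumerate(rng.integers(0, 4, size=width)):
        probs[j, b] = consensus_prob
    return Pwm(name, probs)


def sample_site(pwm: Pwm, strength: float, rng: np.random.Generator) -> str:
    """Draw a site: each position is the consensus base with probability
    ``strength``, otherwise a draw from the motif's own distribution."""
    consensus = pwm.consensus()
    out = []
    for j in range(pwm.width):
        if rng.random() < strength:
            out.append(consensus[j])
        else:
            out.append(BASES[rng.choice(4, p=pwm.probs[j])])
    return "".join(out)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=probs)])


def gen_chip_windows(
    pwm: Pwm,
    n_pos: int = 150,
    n_neg: int = 150,
    site_strength_range: tuple[float, float] = (0.7, 1.0),
    noise_sd: float = 0.05,
    tau_true: float = 2.0,
    eT_true: float = 3.0,
    window_length: int = 500,
    gc: float = 0.41,
    seed: int = 0,
    decoy_pwm: Pwm | None = None,
) -> tuple[list[LabeledWindow], dict]:
    """ChIP-like training windows with planted sites and analytic signal.

    Positives carry 1-3 sites sampled from the PWM at strengths drawn from
    ``site_strength_range``; negatives are motif-free background (or carry
    decoy-motif sites when ``decoy_pwm`` is given).  Every window's
    chip_signal is its occupancy under ``OccupancyModel(pwm, tau_true,
    eT_true)`` plus Normal(0, noise_sd) noise.  The truth mapping records
    planted site offsets per window.
    """
    rng = np.random.default_rng(seed)
    truth_model = OccupancyModel(pwm, tau=tau_true, eT=eT_true)
    windows: list[LabeledWindow] = []
    truth: dict = {"tau_true": tau_true, "eT_true": eT_true, "sites": {}}

    def emit(label: str, seq: str, offsets: list[int]) -> None:
        signal = truth_model.occupancy(seq)
        if noise_sd > 0:
            signal += rng.normal(0.0, noise_sd)
        wid = f"{label[:3]}_{len(windows):04d}"
        windows.append(LabeledWindow(sequence=seq, chip_signal=signal, label=label))
        truth["sites"][wid] = offsets

    lo, hi = site_strength_range
    for _ in range(n_pos):
        seq = list(_random_seq(rng, window_length, gc))
        offsets = []
        for _ in range(rng.integers(1, 4)):
            site = sample_site(pwm, rng.uniform(lo, hi), rng)
            off = int(rng.integers(0, window_length - pwm.width + 1))
            seq[off : off + pwm.width] = site
            offsets.append(off)
        emit("positive", "".join(seq), offsets)
    for _ in range(n_neg):
        seq = list(_random_seq(rng, window_length, gc))
        offsets = []
        if decoy_pwm is not None:
            site = sample_site(decoy_pwm, rng.uniform(lo, hi), rng)
            off = int(rng.integers(0, window_length - decoy_pwm.width + 1))
            seq[off : off + decoy_pwm.width] = site
        emit("negative", "".join(seq), offsets)
    return windows, truth


def gen_asb_benchmark(
    pwm: Pwm,
    n_per_class: int = 200,
    window_length: int = 501,
    gc: float = 0.41,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Allele window pairs for impact-score evaluation.

    Positives plant a consensus site covering the window center and the
    minor allele replaces the most informative in-site base with the least
    preferred one (a site-destroying SNP).  Negatives are matched SNPs in
    motif-free background.  Returns (pairs, labels) with pairs =
    (major_seq, minor_seq).
    """
    rng = np.random.default_rng(seed)
    center = window_length // 2
    consensus = pwm.consensus()
    info = np.ptp(np.log(pwm.probs), axis=1)
    j_star = int(np.argmax(info))
    worst = BASES[int(np.argmin(pwm.probs[j_star]))]

    pairs: list[tuple[str, str]] = []
    labels = np.concatenate([np.ones(n_per_class, int), np.zeros(n_per_class, int)])
    for _ in range(n_per_class):
        seq = list(_random_seq(rng, window_length, gc))
        off = center - j_star  # SNP position falls on motif column j_star
        seq[off : off + pwm.width] = consensus
        major = "".join(seq)
        minor = major[:center] + worst + major[center + 1 :]
        pairs.append((major, minor))
    for _ in range(n_per_class):
        seq = _random_seq(rng, window_length, gc)
        major_base = seq[center]
        alt = BASES[(BASES.index(major_base) + 1 + rng.integers(0, 3)) % 4]
        minor = seq[:center] + alt + seq[center + 1 :]
        pairs.append((seq, minor))
    return pairs, labels


# ---------------------------------------------------------------------------
# The full cohort study
# ---------------------------------------------------------------------------


@dataclass
class Study:
    """A complete synthetic study: every input the pipeline consumes."""

    genome: dict[str, str]
    pwms: dict[str, Pwm]
    peaks: dict[str, list[GenomicInterval]]
    dhs: list[GenomicInterval]
    domains: list[GenomicInterval]
    loops: list[LoopPair]
    genes: dict[str, GenomicInterval]
    snps: list[SnpRecord]
    cohort: CohortData
    drugs: list[str]
    truth: dict


def _plant_site(seq: list[str], pos: int, site: str) -> None:
    seq[pos : pos + len(site)] = site


def simulate_study(seed: int = 0, preset: str = "tiny", **overrides) -> Study:
    """Generate the tiny-preset cohort study with one planted causal chain.

    The causal TF's binding sites in the causal genes' chromatin domains
    carry site-destroying SNPs; each causal gene's expression is an additive
    function of its causal SNP dosages, and the causal drug's EC50 loads on
    the causal genes' expression.  All other SNPs, genes and drugs are noise.
    """
    if preset != "tiny":
        raise ValueError(f"unknown preset {preset!r}")
    cfg = dict(TINY, **overrides)
    rng = np.random.default_rng(seed)

    chrom = cfg["chrom"]
    length = cfg["length"]
    dsize = cfg["domain_size"]
    half_peak = cfg["peak_half_width"]
    w = cfg["motif_width"]
    tf_a, tf_b = cfg["tfs"]
    causal_tf = cfg["causal_tf"]
    causal_drug = cfg["causal_drug"]
    n_causal = cfg["n_causal_genes"]

    genome_chars = list(_random_seq(rng, length, cfg["gc"]))
    pwms = {
        tf_a: random_pwm(w, cfg["consensus_prob"], seed=int(rng.integers(2**31)), name=tf_a),
        tf_b: random_pwm(w, cfg["consensus_prob"], seed=int(rng.integers(2**31)), name=tf_b),
    }

    n_domains = length // dsize
    domains = [
        GenomicInterval(chrom, d * dsize, (d + 1) * dsize, name=f"domain_{d}")
        for d in range(n_domains)
    ]
    # two genes per domain; causal genes sit alone in domains 0..n_causal-1
    genes: dict[str, GenomicInterval] = {}
    for g in range(2 * n_domains):
        start = g * (dsize // 2) + 1000
        genes[f"gene_{g:03d}"] = GenomicInterval(chrom, start, start + 2000, name=f"gene_{g:03d}")
    causal_genes = [f"gene_{2 * d:03d}" for d in range(n_causal)]

    snps: list[SnpRecord] = []
    peaks: dict[str, list[GenomicInterval]] = {tf_a: [], tf_b: []}
    causal_snps_by_gene: dict[str, list[str]] = {g: [] for g in causal_genes}
    binding_snps: dict[str, list[str]] = {tf_a: [], tf_b: []}
    snp_count = 0
    occupied: set[int] = set()

    def new_snp(pos0: int, major: str, minor: str, maf: float) -> str:
        """Register a SNP at 0-based position pos0; returns its id."""
        nonlocal snp_count
        sid = f"rs{snp_count:05d}"
        snp_count += 1
        occupied.add(pos0)
        genome_chars[pos0] = major
        snps.append(SnpRecord(sid, chrom, pos0 + 1, major, minor, maf=maf))
        return sid

    def background_snp(pos0: int) -> str:
        major = genome_chars[pos0]
        minor = BASES[(BASES.index(major) + 1 + int(rng.integers(0, 3))) % 4]
        return new_snp(pos0, major, minor, float(rng.uniform(0.1, 0.45)))

    def plant_peak(tf: str, center: int, destroying_snp: bool, n_background: int) -> str | None:
        """Plant a consensus site + peak; optionally a site-destroying SNP
        and ``n_background`` in-peak background SNPs.  Returns the causal
        SNP id (or None)."""
        pwm = pwms[tf]
        consensus = pwm.consensus()
        _plant_site(genome_chars, center, consensus)
        peaks[tf].append(
            GenomicInterval(chrom, center - half_peak, center + half_peak, name=tf)
        )
        sid = None
        if destroying_snp:
            info = np.ptp(np.log(pwm.probs), axis=1)
            j_star = int(np.argmax(info))
            worst = BASES[int(np.argmin(pwm.probs[j_star]))]
            sid = new_snp(center + j_star, consensus[j_star], worst, cfg["causal_maf"])
            binding_snps[tf].append(sid)
        placed = 0
        while placed < n_background:
            pos0 = center + int(rng.integers(-half_peak + 5, half_peak - 5))
            in_site = center - 1 <= pos0 <= center + w  # keep clear of the site
            if pos0 in occupied or in_site:
                continue
            background_snp(pos0)
            placed += 1
        return sid

    # causal TF peaks: 3 per causal-gene domain, each with a destroying SNP
    peak_offsets = (5000, 11_000, 17_000)
    for d, gene in enumerate(causal_genes):
        for off in peak_offsets:
            sid = plant_peak(causal_tf, d * dsize + off, destroying_snp=True, n_background=3)
            causal_snps_by_gene[gene].append(sid)
    # non-causal TF_A peaks in the remaining domains: sites but no destroying SNPs
    for d in range(n_causal, n_domains):
        for off in peak_offsets:
            plant_peak(tf_a, d * dsize + off, destroying_snp=False, n_background=3)
    # TF_B peaks with destroying SNPs that are NOT wired to expression
    for d in range(n_causal, n_domains):
        for off in (6800, 12_800, 18_800):
            plant_peak(tf_b, d * dsize + off, destroying_snp=True, n_background=2)

    # one loop: the first causal gene also reads a distal anchor carrying an
    # extra causal-TF peak with a destroying SNP
    anchor_gene = genes[causal_genes[0]]
    distal_center = length - 2500
    loop_sid = plant_peak(causal_tf, distal_center, destroying_snp=True, n_background=1)
    causal_snps_by_gene[causal_genes[0]].append(loop_sid)
    loops = [
        LoopPair(
            GenomicInterval(chrom, anchor_gene.start, anchor_gene.end, name="loop_a1"),
            GenomicInterval(chrom, distal_center - 500, distal_center + 500, name="loop_a2"),
        )
    ]

    # free-floating accessible background SNPs
    n_free = 100
    while n_free > 0:
        pos0 = int(rng.integers(500, length - 500))
        if pos0 in occupied:
            continue
        background_snp(pos0)
        n_free -= 1

    genome = {chrom: "".join(genome_chars)}
    dhs = sorted(
        GenomicInterval(chrom, max(0, s.pos - 1 - 100), min(length, s.pos - 1 + 101), name="dhs")
        for s in snps
    )

    # ---- cohort ----
    n_samples = cfg["n_samples"]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    snp_ids = [s.snp_id for s in snps]
    dosage = np.array(
        [rng.binomial(2, s.maf, size=n_samples) for s in snps], dtype=float
    )
    genotypes = pd.DataFrame(dosage, index=snp_ids, columns=samples)

    gene_ids = sorted(genes)
    expr = rng.normal(0.0, 1.0, size=(len(gene_ids), n_samples))
    expression = pd.DataFrame(expr, index=gene_ids, columns=samples)
    beta_e = cfg["beta_eqtl"]
    for gene, sids in causal_snps_by_gene.items():
        drive = sum(genotypes.loc[sid].to_numpy() for sid in sids)
        expression.loc[gene] = beta_e * (drive - drive.mean()) + rng.normal(
            0.0, 1.0, size=n_samples
        )

    drugs = list(cfg["drugs"])
    pheno = rng.normal(0.0, 1.0, size=(len(drugs), n_samples))
    phenotypes = pd.DataFrame(pheno, index=drugs, columns=samples)
    beta_p = cfg["beta_pheno"]
    load = sum(expression.loc[g].to_numpy() for g in causal_genes)
    phenotypes.loc[causal_drug] = beta_p * load + rng.normal(0.0, 1.0, size=n_samples)

    cohort = CohortData(
        samples=samples,
        genotypes=genotypes,
        expression=expression,
        phenotypes=phenotypes,
    )

    truth = {
        "causal_tf": causal_tf,
        "causal_drug": causal_drug,
        "causal_genes": causal_genes,
        "causal_snps": {g: list(s) for g, s in causal_snps_by_gene.items()},
        "binding_snps": {tf: list(s) for tf, s in binding_snps.items()},
        "beta_eqtl": beta_e,
        "beta_pheno": beta_p,
        "top_k": cfg["top_k"],
        "seed": seed,
    }
    return Study(
        genome=genome,
        pwms=pwms,
        peaks=peaks,
        dhs=dhs,
        domains=domains,
        loops=loops,
        genes=genes,
        snps=snps,
        cohort=cohort,
        drugs=drugs,
        truth=truth,
    )


def write_study(study: Study, outdir: str | Path) -> None:
    """Write every study input in its standard on-disk format plus the truth
    sidecar (JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(study.genome, out / "genome.fa")
    write_pwm_set(list(study.pwms.values()), out / "motifs.txt")
    for tf, peaks in study.peaks.items():
        write_intervals(peaks, out / f"peaks_{tf}.bed", kind="bed")
    write_intervals(study.dhs, out / "dhs.bed", kind="bed")
    write_intervals(study.domains, out / "domains.bed", kind="bed")
    write_intervals(study.loops, out / "loops.bedpe", kind="bedpe")
    write_intervals(list(study.genes.values()), out / "genes.bed", kind="bed")
    write_snp_table(study.snps, out / "snps.tsv")
    write_matrix(study.cohort.genotypes, out / "genotypes.tsv")
    write_matrix(study.cohort.expression, out / "expression.tsv")
    write_matrix(study.cohort.phenotypes, out / "phenotypes.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=2)
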