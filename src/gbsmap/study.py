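"""Composite desk-scale replication studies.

These runners wire the whole method together on synthetic data at a scale a
single CPU handles in minutes: simulate an inbred cross and its GBS run once,
then genotype, map and scaffold one or more draft-assembly variants of the
same data (the expensive read scan is shared across variants because
diagnostic-pair counts are assembly-independent).

Used by the example scripts, the acceptance tooling and the heavier
integration tests.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import genotyping, linkmap, markers, scaffold, simulate

__all__ = ["FinishingStudyResult", "run_finishing_study", "run_demux_study"]


@dataclass
class AssemblyResult:
    """Mapping/scaffolding outcome for one draft-assembly variant."""

    n_linkage_groups: int
    n_singletons: int
    n_pseudomolecules: int
    n_contigs_broken: int
    breakpoints: pd.DataFrame
    placements: pd.DataFrame
    pseudomolecules: dict[str, str]
    map_lengths_cm: dict[str, float]
    evaluation: dict


@dataclass
class FinishingStudyResult:
    truth: simulate.TruthSet
    config: simulate.SimConfig
    n_markers: int
    demux_counts: pd.Series
    clean: AssemblyResult | None = None
    chimeric: AssemblyResult | None = None


def _analyse_assembly(
    contigs: dict[str, str],
    marker_frame: pd.DataFrame,
    pair_counts: pd.DataFrame,
    individuals: list[str],
    truth: simulate.TruthSet,
    k: int,
    window: int,
    min_allele: int,
    min_calls: int,
    min_locus_informative: int,
    distortion_alpha: float,
    max_rf: float,
    min_lod: float,
    min_switch: float,
    min_informative: int,
    gap: int,
) -> AssemblyResult:
    placed, _rejected = markers.place_markers(marker_frame, contigs)
    counts = genotyping.pair_counts_to_alleles(pair_counts, placed)
    calls = genotyping.call_genotypes(counts, min_allele=min_allele)
    lengths = {n: len(s) for n, s in contigs.items()}
    matrix = genotyping.bin_consensus(
        calls, lengths, window=window, min_calls=min_calls, individuals=individuals
    )

    informative = (matrix.codes != genotyping.U).sum(axis=1)
    pvals = linkmap.segregation_pvalues(matrix)
    keep = np.flatnonzero(
        (informative >= min_locus_informative) & (pvals >= distortion_alpha)
    )
    sub = genotyping.GenotypeMatrix(
        loci=matrix.loci.iloc[keep].reset_index(drop=True),
        individuals=matrix.individuals,
        codes=matrix.codes[keep],
    )
    rf = linkmap.pairwise_rf(sub)
    groups = linkmap.group_loci(rf["r"], rf["lod"], max_rf=max_rf, min_lod=min_lod)
    usable = [g for g in groups if g.size >= 2]
    ordered = [linkmap.order_loci(g, rf["r"], rf["n"]) for g in usable]
    gmap = linkmap.build_genetic_map(ordered, rf["r"])

    breakpoints = scaffold.detect_misjoins(
        matrix,
        min_switch=min_switch,
        min_informative=min_informative,
        distortion_alpha=distortion_alpha,
    )
    split, provenance = scaffold.split_contigs(contigs, breakpoints, window=window)
    locus_map = scaffold.locus_map_frame(gmap, sub)
    locus_map = scaffold.relabel_loci_after_split(locus_map, provenance)
    placements = scaffold.place_contigs(locus_map, sorted(split))
    pseudos, agp, _unplaced = scaffold.build_pseudomolecules(placements, split, gap=gap)
    scaffold.validate_agp(agp, {n: len(s) for n, s in split.items()})

    # consensus/map loci carry pre-split contig names; placements post-split
    evaluation = ev.evaluate_against_truth(
        truth, consensus=sub, genetic_map=gmap, breakpoints=breakpoints, window=window
    )
    evaluation.update(
        ev.evaluate_against_truth(
            truth, placements=placements, provenance=provenance, window=window
        )
    )
    return AssemblyResult(
        n_linkage_groups=len(usable),
        n_singletons=sum(1 for g in groups if g.size == 1),
        n_pseudomolecules=len(pseudos),
        n_contigs_broken=int(breakpoints["contig"].nunique()),
        breakpoints=breakpoints,
        placements=placements,
        pseudomolecules=pseudos,
        map_lengths_cm={g.name: g.length_cm for g in gmap.groups},
        evaluation=evaluation,
    )


def run_finishing_study(
    seed: int = 0,
    n_chromosomes: int = 9,
    chromosome_length: int = 500_000,
    snv_rate: float = 0.002,
    n_individuals: int = 96,
    crossover_mean: float = 1.5,
    mean_depth: float = 4.0,
    n_contigs: int = 60,
    n_chimeras: int = 3,
    min_contig_length: int = 2_000,
    k: int = 51,
    window: int = 14_000,
    min_allele: int = 2,
    min_calls: int = 2,
    min_locus_informative: int = 10,
    distortion_alpha: float = 1e-6,
    max_rf: float = 0.35,
    min_lod: float = 6.0,
    min_switch: float = 0.5,
    min_informative: int = 20,
    gap: int = 100,
    workdir: str | None = None,
    variants: tuple[str, ...] = ("clean", "chimeric"),
) -> FinishingStudyResult:
    """Simulate one F2 GBS study and finish one or two assembly variants.

    ``clean`` fragments parent A into ``n_contigs`` intact contigs;
    ``chimeric`` fragments the same genome into ``n_contigs`` contigs of
    which ``n_chimeras`` are engineered cross-chromosome joins.  Both
    variants share the simulated reads, demultiplexing and the k-mer scan.
    """
    cfg = simulate.SimConfig(
        n_chromosomes=n_chromosomes,
        chromosome_length=chromosome_length,
        snv_rate=snv_rate,
        n_individuals=n_individuals,
        crossover_mean=crossover_mean,
        mean_depth=mean_depth,
        n_contigs=n_contigs,
        chimeras=0,
        min_contig_length=min_contig_length,
        seed=seed,
    )
    truth = simulate.simulate_parents(cfg)
    simulate.simulate_f2_population(truth, cfg)

    counts_a = markers.count_kmers(list(truth.haplotype_a.values()), k)
    counts_b = markers.count_kmers(list(truth.haplotype_b.values()), k)
    marker_frame = markers.discover_markers(counts_a, counts_b)

    own_tmp = workdir is None
    workdir = workdir or tempfile.mkdtemp(prefix="gbsmap_study_")
    os.makedirs(workdir, exist_ok=True)
    fastq = os.path.join(workdir, "gbs.fastq")
    simulate.simulate_gbs_run(truth, cfg, fastq)
    demux = genotyping.demultiplex(fastq, cfg.barcodes, outdir=os.path.join(workdir, "demux"))
    reads = {s: p for s, p in demux.paths.items() if s != "unassigned"}
    pair_counts = genotyping.count_pair_hits(reads, marker_frame, k)

    result = FinishingStudyResult(
        truth=truth,
        config=cfg,
        n_markers=int(marker_frame["pair_id"].nunique()),
        demux_counts=demux.counts,
    )
    kwargs = dict(
        marker_frame=marker_frame,
        pair_counts=pair_counts,
        individuals=cfg.sample_ids,
        truth=truth,
        k=k,
        window=window,
        min_allele=min_allele,
        min_calls=min_calls,
        min_locus_informative=min_locus_informative,
        distortion_alpha=distortion_alpha,
        max_rf=max_rf,
        min_lod=min_lod,
        min_switch=min_switch,
        min_informative=min_informative,
        gap=gap,
    )
    if "clean" in variants:
        contigs, _, _ = simulate.fragment_reference(truth, cfg, chimeras=[])
        result.clean = _analyse_assembly(contigs, **kwargs)
    if "chimeric" in variants and n_chimeras > 0:
        contigs, _, _ = simulate.fragment_reference(
            truth,
            simulate.SimConfig(**{**_cfg_dict(cfg), "chimeras": n_chimeras}),
        )
        result.chimeric = _analyse_assembly(contigs, **kwargs)
    if own_tmp:
        import shutil

        shutil.rmtree(workdir, ignore_errors=True)
    return result


def _cfg_dict(cfg: simulate.SimConfig) -> dict:
    import dataclasses

    return dataclasses.asdict(cfg)


def run_demux_study(
    seed: int = 0,
    n_individuals: int = 288,
    n_chromosomes: int = 2,
    chromosome_length: int = 100_000,
    mean_depth: float = 2.0,
    workdir: str | None = None,
) -> pd.Series:
    """Simulate a fully multiplexed GBS run and demultiplex it.

    Returns the per-sample read counts (plus 'unassigned'); the headline
    number is how many of the barcoded individuals received at least one
    read.
    """
    cfg = simulate.SimConfig(
        n_chromosomes=n_chromosomes,
        chromosome_length=chromosome_length,
        snv_rate=0.002,
        n_individuals=n_individuals,
        mean_depth=mean_depth,
        n_contigs=max(4, n_chromosomes * 2),
        seed=seed,
    )
    truth = simulate.simulate_parents(cfg)
    simulate.simulate_f2_population(truth, cfg)
    own_tmp = workdir is None
    workdir = workdir or tempfile.mkdtemp(prefix="gbsmap_demux_")
    os.makedirs(workdir, exist_ok=True)
    fastq = os.path.join(workdir, "gbs.fastq")
    simulate.simulate_gbs_run(truth, cfg, fastq)
    demux = genotyping.demultiplex(fastq, cfg.barcodes, outdir=os.path.join(workdir, "demux"))
    counts = demux.counts
    if own_tmp:
        import shutil

        shutil.rmtree(workdir, ignore_errors=True)
    return counts
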