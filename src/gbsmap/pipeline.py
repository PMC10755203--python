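"""Pipeline orchestration: configuration, stages, manifest.

Stages communicate exclusively through files in the run directory, so no
stage can mutate an upstream output and every stage can be rerun
independently.  All randomness flows from the single config seed (each
simulator substage derives its own stream), so a rerun with an identical
config reproduces byte-identical outputs.

Stage order: simulate -> discover -> demux -> genotype -> bin -> map -> qc
-> scaffold -> evaluate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import genotyping, io, linkmap, markers, scaffold, simulate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES", "load_truth"]

STAGES = [
    "simulate",
    "discover",
    "demux",
    "genotype",
    "bin",
    "map",
    "qc",
    "scaffold",
    "evaluate",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Every stage parameter plus the run directory; round-trips through a
    single YAML file (unknown keys rejected)."""

    outdir: str = "gbsmap_run"
    seed: int = 0
    # simulation
    n_chromosomes: int = 9
    chromosome_length: int = 500_000
    snv_rate: float = 0.002
    n_individuals: int = 288
    crossover_mean: float = 1.5
    read_length: int = 100
    error_rate: float = 0.0
    mean_depth: float = 4.0
    size_selection: tuple[int, int] = (60, 400)
    n_contigs: int = 60
    chimeras: int = 0
    chimera_seg_range: tuple[int, int] = (30_000, 80_000)
    min_contig_length: int = 2_000
    # markers
    k: int = 51
    min_count: int = 1
    max_other: int = 0
    # genotyping
    max_mismatch: int = 0
    min_allele: int = 2
    window: int = 14_000
    min_calls: int = 2
    # linkage map
    min_locus_informative: int = 10
    distortion_alpha: float = 1e-6
    max_rf: float = 0.35
    min_lod: float = 6.0
    # misjoin qc
    min_switch: float = 0.5
    min_informative: int = 20
    # scaffolding
    gap: int = 100

    def sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(
            n_chromosomes=self.n_chromosomes,
            chromosome_length=self.chromosome_length,
            snv_rate=self.snv_rate,
            n_individuals=self.n_individuals,
            crossover_mean=self.crossover_mean,
            read_length=self.read_length,
            error_rate=self.error_rate,
            mean_depth=self.mean_depth,
            size_selection=tuple(self.size_selection),
            n_contigs=self.n_contigs,
            chimeras=self.chimeras,
            chimera_seg_range=tuple(self.chimera_seg_range),
            min_contig_length=self.min_contig_length,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["size_selection"] = list(d["size_selection"])
        d["chimera_seg_range"] = list(d["chimera_seg_range"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("size_selection", "chimera_seg_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _p(cfg: PipelineConfig, name: str) -> str:
    return os.path.join(cfg.outdir, name)


def _require(cfg: PipelineConfig, files: dict[str, str], stage: str) -> None:
    for fname, producer in files.items():
        if not os.path.exists(_p(cfg, fname)):
            raise PipelineError(
                f"stage '{stage}' needs {fname!r}; run stage '{producer}' first"
            )


def load_truth(cfg: PipelineConfig) -> simulate.TruthSet:
    """Reload a TruthSet written by the simulate stage."""
    parents = io.read_fasta(_p(cfg, "parents.fa"))
    hap_a = {n[:-2]: s for n, s in parents.items() if n.endswith("_A")}
    hap_b = {n[:-2]: s for n, s in parents.items() if n.endswith("_B")}
    truth = simulate.TruthSet(
        haplotype_a=hap_a,
        haplotype_b=hap_b,
        snv_table=io.read_tsv(_p(cfg, "truth_snv.tsv")),
        gametes=io.read_tsv(_p(cfg, "truth_gametes.tsv")),
    )
    truth.individuals = sorted(truth.gametes["individual"].unique())
    layout_path = _p(cfg, "truth_layout.tsv")
    if os.path.exists(layout_path):
        truth.contig_layout = io.read_tsv(layout_path)
    chim_path = _p(cfg, "truth_chimeras.tsv")
    if os.path.exists(chim_path):
        truth.chimera_truth = io.read_tsv(chim_path)
    return truth


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> None:
    sc = cfg.sim_config()
    truth = simulate.simulate_parents(sc)
    simulate.simulate_f2_population(truth, sc)
    contigs, layout, chim = simulate.fragment_reference(truth, sc)
    parents = {}
    for chrom in truth.haplotype_a:
        parents[f"{chrom}_A"] = truth.haplotype_a[chrom]
        parents[f"{chrom}_B"] = truth.haplotype_b[chrom]
    io.write_fasta(parents, _p(cfg, "parents.fa"))
    io.write_fasta(contigs, _p(cfg, "contigs.fa"))
    io.write_tsv(pd.DataFrame(sc.barcodes, columns=["sample_id", "barcode"]), _p(cfg, "barcodes.tsv"))
    io.write_tsv(truth.snv_table, _p(cfg, "truth_snv.tsv"))
    io.write_tsv(truth.gametes, _p(cfg, "truth_gametes.tsv"))
    io.write_tsv(layout, _p(cfg, "truth_layout.tsv"))
    io.write_tsv(chim, _p(cfg, "truth_chimeras.tsv"))
    simulate.simulate_gbs_run(truth, sc, _p(cfg, "gbs.fastq"))


def stage_discover(cfg: PipelineConfig) -> None:
    _require(cfg, {"parents.fa": "simulate", "contigs.fa": "simulate"}, "discover")
    parents = io.read_fasta(_p(cfg, "parents.fa"))
    seqs_a = [s for n, s in parents.items() if n.endswith("_A")]
    seqs_b = [s for n, s in parents.items() if n.endswith("_B")]
    counts_a = markers.count_kmers(seqs_a, cfg.k)
    counts_b = markers.count_kmers(seqs_b, cfg.k)
    marker_frame = markers.discover_markers(
        counts_a, counts_b, min_count=cfg.min_count, max_other=cfg.max_other
    )
    io.write_tsv(marker_frame, _p(cfg, "markers.tsv"))
    contigs = io.read_fasta(_p(cfg, "contigs.fa"))
    placed, rejected = markers.place_markers(marker_frame, contigs)
    io.write_tsv(placed, _p(cfg, "placed.tsv"))
    io.write_tsv(rejected, _p(cfg, "rejected_markers.tsv"))
    bed = placed[placed["parent"] == "A"][["contig", "start"]].copy()
    bed["end"] = bed["start"] + cfg.k
    merged = placed[placed["parent"] == "A"]
    bed["name"] = merged["marker_id"].to_numpy()
    bed["score"] = merged["snv_offset"].to_numpy()
    bed["strand"] = merged["strand"].to_numpy()
    bed.to_csv(_p(cfg, "placed.bed"), sep="\t", header=False, index=False)


def stage_demux(cfg: PipelineConfig) -> None:
    _require(cfg, {"gbs.fastq": "simulate", "barcodes.tsv": "simulate"}, "demux")
    barcodes = io.read_tsv(_p(cfg, "barcodes.tsv"))
    res = genotyping.demultiplex(
        _p(cfg, "gbs.fastq"),
        barcodes,
        outdir=_p(cfg, "demux"),
        max_mismatch=cfg.max_mismatch,
    )
    io.write_tsv(
        res.counts.rename_axis("sample_id").reset_index(), _p(cfg, "demux_summary.tsv")
    )


def stage_genotype(cfg: PipelineConfig) -> None:
    _require(
        cfg,
        {"placed.tsv": "discover", "markers.tsv": "discover", "demux_summary.tsv": "demux"},
        "genotype",
    )
    placed = io.read_tsv(_p(cfg, "placed.tsv"))
    marker_frame = io.read_tsv(_p(cfg, "markers.tsv"))
    barcodes = io.read_tsv(_p(cfg, "barcodes.tsv"))
    reads = {
        s: os.path.join(_p(cfg, "demux"), f"{s}.fastq") for s in barcodes["sample_id"]
    }
    counts = genotyping.count_alleles(reads, placed, marker_frame, cfg.k)
    calls = genotyping.call_genotypes(counts, min_allele=cfg.min_allele)
    io.write_tsv(calls, _p(cfg, "genotypes_raw.tsv"))


def stage_bin(cfg: PipelineConfig) -> None:
    _require(cfg, {"genotypes_raw.tsv": "genotype", "contigs.fa": "simulate"}, "bin")
    calls = io.read_tsv(_p(cfg, "genotypes_raw.tsv"))
    contigs = io.read_fasta(_p(cfg, "contigs.fa"))
    lengths = {n: len(s) for n, s in contigs.items()}
    barcodes = io.read_tsv(_p(cfg, "barcodes.tsv"))
    matrix = genotyping.bin_consensus(
        calls,
        lengths,
        window=cfg.window,
        min_calls=cfg.min_calls,
        individuals=list(barcodes["sample_id"]),
    )
    io.write_tsv(matrix.loci, _p(cfg, "windows.tsv"))
    matrix.write_tsv(_p(cfg, "consensus.tsv"))


def _load_matrix(cfg: PipelineConfig) -> genotyping.GenotypeMatrix:
    loci = io.read_tsv(_p(cfg, "windows.tsv"))
    frame = pd.read_csv(_p(cfg, "consensus.tsv"), sep="\t", index_col=0)
    return genotyping.GenotypeMatrix.from_frame(frame, loci)


def stage_map(cfg: PipelineConfig) -> None:
    _require(cfg, {"consensus.tsv": "bin", "windows.tsv": "bin"}, "map")
    matrix = _load_matrix(cfg)
    informative = (matrix.codes != genotyping.U).sum(axis=1)
    pvals = linkmap.segregation_pvalues(matrix)
    distorted = pvals < cfg.distortion_alpha
    keep = np.flatnonzero((informative >= cfg.min_locus_informative) & ~distorted)
    sub = genotyping.GenotypeMatrix(
        loci=matrix.loci.iloc[keep].reset_index(drop=True),
        individuals=matrix.individuals,
        codes=matrix.codes[keep],
    )
    rf = linkmap.pairwise_rf(sub)
    groups = linkmap.group_loci(rf["r"], rf["lod"], max_rf=cfg.max_rf, min_lod=cfg.min_lod)
    usable = [g for g in groups if g.size >= 2]
    ordered = [linkmap.order_loci(g, rf["r"], rf["n"]) for g in usable]
    gmap = linkmap.build_genetic_map(ordered, rf["r"])
    locus_map = scaffold.locus_map_frame(gmap, sub)
    io.write_tsv(locus_map, _p(cfg, "map.tsv"))
    # long-format cache of the pairwise estimates
    iu, ju = np.triu_indices(len(sub.loci), k=1)
    rf_long = pd.DataFrame(
        {
            "locus_i": iu,
            "locus_j": ju,
            "r": rf["r"][iu, ju],
            "lod": rf["lod"][iu, ju],
            "n": rf["n"][iu, ju].astype(int),
        }
    )
    io.write_tsv(rf_long, _p(cfg, "rf.tsv"))
    n_singleton = sum(1 for g in groups if g.size == 1)
    io.write_tsv(
        pd.DataFrame(
            {
                "n_groups": [len(usable)],
                "n_singletons": [n_singleton],
                "n_loci_mapped": [int(sum(len(g) for g in usable))],
                "n_distorted_flagged": [int(distorted.sum())],
            }
        ),
        _p(cfg, "map_summary.tsv"),
    )
    # segregation-distortion flags, reported per window (not filtered calls)
    flags = matrix.loci.copy()
    flags["segregation_p"] = pvals
    flags["distorted"] = distorted
    io.write_tsv(flags, _p(cfg, "distortion_flags.tsv"))


def stage_qc(cfg: PipelineConfig) -> None:
    _require(cfg, {"consensus.tsv": "bin", "contigs.fa": "simulate"}, "qc")
    matrix = _load_matrix(cfg)
    breakpoints = scaffold.detect_misjoins(
        matrix, min_switch=cfg.min_switch, min_informative=cfg.min_informative
    )
    io.write_tsv(breakpoints, _p(cfg, "breakpoints.tsv"))
    contigs = io.read_fasta(_p(cfg, "contigs.fa"))
    split, provenance = scaffold.split_contigs(contigs, breakpoints, window=cfg.window)
    io.write_fasta(split, _p(cfg, "contigs_split.fa"))
    io.write_tsv(provenance, _p(cfg, "provenance.tsv"))


def stage_scaffold(cfg: PipelineConfig) -> None:
    _require(
        cfg,
        {"map.tsv": "map", "contigs_split.fa": "qc", "provenance.tsv": "qc"},
        "scaffold",
    )
    locus_map = io.read_tsv(_p(cfg, "map.tsv"))
    provenance = io.read_tsv(_p(cfg, "provenance.tsv"))
    locus_map = scaffold.relabel_loci_after_split(locus_map, provenance)
    parts = io.read_fasta(_p(cfg, "contigs_split.fa"))
    placements = scaffold.place_contigs(locus_map, sorted(parts))
    io.write_tsv(placements, _p(cfg, "placements.tsv"))
    pseudos, agp, unplaced = scaffold.build_pseudomolecules(placements, parts, gap=cfg.gap)
    scaffold.validate_agp(agp, {n: len(s) for n, s in parts.items()})
    io.write_fasta(pseudos, _p(cfg, "pseudomolecules.fa"))
    io.write_fasta(unplaced, _p(cfg, "unplaced.fa"))
    with open(_p(cfg, "assembly.agp"), "w") as fh:
        fh.write("##agp-version\t2.1\n")
        agp.to_csv(fh, sep="\t", header=False, index=False)


def stage_evaluate(cfg: PipelineConfig) -> None:
    _require(
        cfg,
        {"consensus.tsv": "bin", "truth_snv.tsv": "simulate"},
        "evaluate",
    )
    truth = load_truth(cfg)
    matrix = _load_matrix(cfg)
    report = ev.evaluate_against_truth(truth, consensus=matrix, window=cfg.window)
    if os.path.exists(_p(cfg, "breakpoints.tsv")):
        bps = io.read_tsv(_p(cfg, "breakpoints.tsv"))
        report.update(
            ev.evaluate_against_truth(truth, breakpoints=bps, window=cfg.window)
        )
    if os.path.exists(_p(cfg, "placements.tsv")) and os.path.exists(_p(cfg, "provenance.tsv")):
        placements = io.read_tsv(_p(cfg, "placements.tsv"))
        provenance = io.read_tsv(_p(cfg, "provenance.tsv"))
        report.update(
            ev.evaluate_against_truth(
                truth, placements=placements, provenance=provenance, window=cfg.window
            )
        )
    with open(_p(cfg, "evaluation.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=float)


_STAGE_FN = {
    "simulate": stage_simulate,
    "discover": stage_discover,
    "demux": stage_demux,
    "genotype": stage_genotype,
    "bin": stage_bin,
    "map": stage_map,
    "qc": stage_qc,
    "scaffold": stage_scaffold,
    "evaluate": stage_evaluate,
}

_MANIFEST_FILES = [
    "parents.fa",
    "contigs.fa",
    "gbs.fastq",
    "barcodes.tsv",
    "truth_snv.tsv",
    "truth_gametes.tsv",
    "truth_layout.tsv",
    "truth_chimeras.tsv",
    "markers.tsv",
    "placed.tsv",
    "placed.bed",
    "rejected_markers.tsv",
    "demux_summary.tsv",
    "distortion_flags.tsv",
    "genotypes_raw.tsv",
    "windows.tsv",
    "consensus.tsv",
    "map.tsv",
    "rf.tsv",
    "map_summary.tsv",
    "breakpoints.tsv",
    "contigs_split.fa",
    "provenance.tsv",
    "placements.tsv",
    "pseudomolecules.fa",
    "unplaced.fa",
    "assembly.agp",
    "evaluation.json",
]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for blk in iter(lambda: fh.read(1 << 20), b""):
            h.update(blk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, stages: list[str] | str = "all") -> dict:
    """Run the requested stages in dependency order; returns the manifest."""
    if stages == "all":
        wanted = list(STAGES)
    else:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        wanted = [s for s in STAGES if s in set(stages)]
    os.makedirs(cfg.outdir, exist_ok=True)
    for stage in wanted:
        _STAGE_FN[stage](cfg)
    from . import __version__

    import numpy, pandas, scipy

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": wanted,
        "versions": {
            "gbsmap": __version__,
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
        },
        "outputs": {
            f: _sha256(_p(cfg, f)) for f in _MANIFEST_FILES if os.path.exists(_p(cfg, f))
        },
    }
    with open(_p(cfg, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
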