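"""Simulator behaviour: parents, F2 segregation, digestion, reads, assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chisquare

from gbsmap.kmers import revcomp
from gbsmap.simulate import (
    ChimeraSpec,
    SimConfig,
    digest_genome,
    fragment_reference,
    parse_read_id,
    simulate_f2_population,
    simulate_gbs_run,
    simulate_parents,
)


def _cfg(**kw):
    base = dict(
        n_chromosomes=1,
        chromosome_length=20_000,
        snv_rate=0.005,
        n_individuals=6,
        crossover_mean=1.0,
        mean_depth=5.0,
        n_contigs=3,
        min_contig_length=1_000,
        seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


# -- parents ---------------------------------------------------------------


def test_zero_snv_rate_gives_identical_haplotypes():
    truth = simulate_parents(_cfg(snv_rate=0.0, chromosome_length=1_000))
    assert truth.haplotype_a == truth.haplotype_b
    assert truth.snv_table.empty


def test_chromosome_count_and_length():
    truth = simulate_parents(_cfg(n_chromosomes=2, chromosome_length=1_500))
    assert sorted(truth.haplotype_a) == ["chr01", "chr02"]
    assert all(len(s) == 1_500 for s in truth.haplotype_a.values())
    assert sorted(truth.haplotype_b) == ["chr01", "chr02"]


def test_snv_count_within_binomial_bounds():
    n, p = 100_000, 0.01
    truth = simulate_parents(_cfg(chromosome_length=n, snv_rate=p, seed=5))
    expected, sd = n * p, np.sqrt(n * p * (1 - p))
    assert abs(len(truth.snv_table) - expected) <= 3 * sd


def test_haplotypes_differ_exactly_at_snv_table():
    truth = simulate_parents(_cfg(seed=3))
    a = np.frombuffer(truth.haplotype_a["chr01"].encode(), np.uint8)
    b = np.frombuffer(truth.haplotype_b["chr01"].encode(), np.uint8)
    assert np.array_equal(
        np.flatnonzero(a != b), truth.snv_table["position"].to_numpy()
    )


# -- F2 population ---------------------------------------------------------


def test_zero_crossover_mean_gives_pure_parental_gametes():
    cfg = _cfg(crossover_mean=0.0)
    truth = simulate_parents(cfg)
    simulate_f2_population(truth, cfg)
    # every gamete is one segment spanning the chromosome
    assert (truth.gametes.groupby(["individual", "chromosome", "gamete"]).size() == 1).all()
    assert (truth.gametes["start"] == 0).all()
    assert (truth.gametes["end"] == cfg.chromosome_length).all()


def test_pure_a_plus_pure_b_individual_is_heterozygous_everywhere():
    cfg = _cfg(crossover_mean=0.0)
    truth = simulate_parents(cfg)
    simulate_f2_population(truth, cfg)
    ind = truth.individuals[0]
    g = truth.gametes
    g.loc[(g.individual == ind) & (g.gamete == 0), "founder"] = 0
    g.loc[(g.individual == ind) & (g.gamete == 1), "founder"] = 1
    truth._gamete_cache = None
    pos, _, _ = truth.snv_arrays("chr01")
    dose = truth.genotype_dosage("chr01", pos)[ind]
    assert (dose == 1).all()


def test_f2_segregation_is_1_2_1():
    cfg = _cfg(chromosome_length=2_000, n_individuals=2_000, snv_rate=0.002, seed=8)
    truth = simulate_parents(cfg)
    simulate_f2_population(truth, cfg)
    pos, _, _ = truth.snv_arrays("chr01")
    dose = truth.genotype_dosage("chr01", pos[:1]).to_numpy().ravel()
    obs = np.bincount(dose, minlength=3)
    n = obs.sum()
    stat = chisquare(obs, f_exp=[n / 4, n / 2, n / 4])
    assert stat.pvalue > 0.001


# -- digestion -------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("TTGCAGCTT", [(0, 3), (3, 9)]),  # GCAGC at index 2, cut at 3
        ("GCAGCTGC", [(0, 1), (1, 4), (4, 8)]),  # overlapping-site scan
        ("AAAATTTT", [(0, 8)]),  # no site: single fragment
        ("", [(0, 0)]),
    ],
)
def test_digest_examples(seq, expected):
    if seq == "":
        assert digest_genome(seq) == [(0, 0)]
    else:
        assert digest_genome(seq) == expected


@given(st.text(alphabet="ACGTN", min_size=1, max_size=300))
def test_digest_round_trip(seq):
    frags = digest_genome(seq)
    assert frags[0][0] == 0 and frags[-1][1] == len(seq)
    assert all(a[1] == b[0] for a, b in zip(frags, frags[1:]))
    assert "".join(seq[s:e] for s, e in frags) == seq


def test_digest_site_set_is_revcomp_closed():
    seq = "TTGCAGCTTTTGCTGCTT"
    rc = revcomp(seq)
    assert len(digest_genome(seq)) == len(digest_genome(rc))


# -- GBS reads -------------------------------------------------------------


@pytest.fixture(scope="module")
def gbs_run(tmp_path_factory):
    cfg = _cfg(n_chromosomes=2, chromosome_length=30_000, seed=4)
    truth = simulate_parents(cfg)
    simulate_f2_population(truth, cfg)
    path = tmp_path_factory.mktemp("gbs") / "run.fastq"
    summary = simulate_gbs_run(truth, cfg, path)
    return cfg, truth, path, summary


def _iter_fastq(path):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def test_error_free_reads_are_mosaic_substrings(gbs_run):
    cfg, truth, path, _ = gbs_run
    barcode_of = dict(cfg.barcodes)
    for title, seq, qual in _iter_fastq(path):
        info = parse_read_id(title)
        bc = barcode_of[info["individual"]]
        assert seq.startswith(bc)
        genomic = seq[len(bc) :]
        mosaic = truth.mosaic_ascii(
            info["individual"], info["chromosome"], info["gamete"]
        ).tobytes().decode()
        if info["strand"] == "T":
            assert mosaic[info["fragment_start"] :].startswith(genomic)
        else:
            assert revcomp(
                mosaic[info["fragment_start"] : info["fragment_end"] + 3]
            ).startswith(genomic)
        assert genomic[:4] in ("CAGC", "CTGC")  # remnant retained
        assert len(seq) <= cfg.read_length
        assert qual == "I" * len(seq)


def test_read_count_conservation(gbs_run):
    cfg, _, path, summary = gbs_run
    n_records = sum(1 for _ in _iter_fastq(path))
    assert n_records == summary["n_reads"] == sum(summary["per_sample"].values())


def test_full_length_reads_have_read_length(gbs_run):
    cfg, _, path, _ = gbs_run
    lengths = [len(seq) for _, seq, _ in _iter_fastq(path)]
    assert max(lengths) == cfg.read_length  # single-end 100 bp by default config


def test_gbs_determinism(tmp_path):
    cfg = _cfg(seed=9)
    out = []
    for run in (1, 2):
        truth = simulate_parents(cfg)
        simulate_f2_population(truth, cfg)
        p = tmp_path / f"r{run}.fastq"
        simulate_gbs_run(truth, cfg, p)
        out.append(p.read_bytes())
    assert out[0] == out[1]


# -- draft assembly --------------------------------------------------------


def test_fragment_reference_round_trip(tiny_cfg, tiny_truth):
    contigs, layout, chim = fragment_reference(tiny_truth, tiny_cfg, chimeras=[])
    assert len(contigs) == tiny_cfg.n_contigs
    assert chim.empty
    assert sum(len(s) for s in contigs.values()) == sum(
        len(s) for s in tiny_truth.haplotype_a.values()
    )
    for chrom, seq in tiny_truth.haplotype_a.items():
        sub = layout[layout.chromosome == chrom].sort_values("start")
        rebuilt = "".join(contigs_part(contigs, layout, r) for r in sub.itertuples())
        assert rebuilt == seq


def contigs_part(contigs, layout, row):
    sub = layout[layout.contig == row.contig].sort_values("part_index")
    offset = 0
    for r in sub.itertuples():
        if r.Index == row.Index:
            return contigs[row.contig][offset : offset + (row.end - row.start)]
        offset += r.end - r.start
    raise AssertionError("layout row not found")


def test_chimera_truth_rows_match_specs(tiny_cfg, tiny_truth):
    cfg = SimConfig(
        **{
            **_asdict(tiny_cfg),
            "chimeras": 3,
            "n_contigs": 12,
            "chimera_seg_range": (5_000, 10_000),
        }
    )
    contigs, layout, chim = fragment_reference(tiny_truth, cfg)
    assert len(chim) == 3
    assert len(contigs) == 12
    for row in chim.itertuples():
        segs = layout[layout.contig == row.contig].sort_values("part_index")
        assert len(segs) == 2
        assert segs.chromosome.nunique() == 2
        first = segs.iloc[0]
        assert row.junction_offset == first.end - first.start


def _asdict(cfg):
    import dataclasses

    return dataclasses.asdict(cfg)


def test_overlapping_chimera_segments_rejected(tiny_cfg, tiny_truth):
    spec = ChimeraSpec(("chr01", 1_000, 9_000), ("chr02", 2_000, 10_000))
    overlap = ChimeraSpec(("chr01", 5_000, 12_000), ("chr02", 30_000, 38_000))
    with pytest.raises(ValueError, match="overlaps an already-consumed"):
        fragment_reference(tiny_truth, tiny_cfg, chimeras=[spec, overlap])


def test_same_chromosome_chimera_rejected():
    with pytest.raises(ValueError, match="different chromosomes"):
        ChimeraSpec(("chr01", 0, 10), ("chr01", 20, 30))


def test_config_validation():
    with pytest.raises(ValueError, match="snv_rate"):
        _cfg(snv_rate=1.5)
    with pytest.raises(ValueError, match="barcode"):
        SimConfig(
            n_chromosomes=1,
            chromosome_length=1_000,
            n_individuals=2,
            barcodes=[("a", "ACGT"), ("b", "ACGT")],
        )
    with pytest.raises(ValueError, match="read_length"):
        _cfg(read_length=10)
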