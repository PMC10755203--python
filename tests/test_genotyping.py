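"""Demultiplexing, allele counting, calling and consensus binning."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gbsmap.genotyping import (
    CODE_LETTERS,
    GenotypeMatrix,
    U,
    bin_consensus,
    call_genotypes,
    count_alleles,
    demultiplex,
)
from gbsmap.markers import count_kmers, discover_markers, place_markers


def _fastq(reads):
    return io.StringIO(
        "".join(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n" for i, s in enumerate(reads))
    )


# -- demultiplex -----------------------------------------------------------


def test_demux_assigns_trims_barcode_keeps_remnant():
    res = demultiplex(_fastq(["ACGTCAGCAAAA"]), [("s1", "ACGT")])
    assert res.counts["s1"] == 1 and res.counts["unassigned"] == 0
    title, seq, qual = res.reads["s1"][0]
    assert seq == "CAGCAAAA"
    assert qual == "I" * len(seq)


def test_demux_requires_remnant_after_barcode():
    res = demultiplex(_fastq(["ACGTTTTTAAAA"]), [("s1", "ACGT")])
    assert res.counts["unassigned"] == 1


def test_demux_longest_barcode_wins():
    res = demultiplex(_fastq(["ACGTCAGCAAAA"]), [("short", "ACG"), ("long", "ACGT")])
    assert res.counts["long"] == 1 and res.counts["short"] == 0


def test_demux_duplicate_barcodes_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        demultiplex(_fastq([]), [("a", "ACGT"), ("b", "ACGT")])


def test_demux_mismatch_tolerance():
    res = demultiplex(_fastq(["AGGTCAGCAAAA"]), [("s1", "ACGT")], max_mismatch=1)
    assert res.counts["s1"] == 1


@given(
    st.lists(st.text(alphabet="ACGT", min_size=1, max_size=30), max_size=25),
    st.lists(
        st.text(alphabet="ACGT", min_size=2, max_size=6), min_size=1, max_size=5, unique=True
    ),
)
def test_demux_partition_property(reads, barcodes):
    table = [(f"s{i}", b) for i, b in enumerate(barcodes)]
    res = demultiplex(_fastq(reads), table)
    assert res.counts.sum() == len(reads)
    total = sum(len(v) for v in res.reads.values())
    assert total == len(reads)


# -- allele counting -------------------------------------------------------


@pytest.fixture(scope="module")
def toy_locus():
    a = "TTGACCATCGGATTACAGAT"
    b = a[:6] + "T" + a[7:]
    k = 7
    m = discover_markers(count_kmers([a], k), count_kmers([b], k))
    placed, _ = place_markers(m, {"c1": a})
    return a, b, m, placed, k


def test_count_alleles_exact_and_mismatch(toy_locus):
    a, b, m, placed, k = toy_locus
    a_kmer = m[m.parent == "A"].kmer.iloc[0]
    b_kmer = m[m.parent == "B"].kmer.iloc[0]
    mut = "G" + a_kmer[1:] if a_kmer[0] != "G" else "T" + a_kmer[1:]
    counts = count_alleles(
        {"s1": [a_kmer, a_kmer, a_kmer, b_kmer, mut]}, placed, m, k
    )
    locus = counts[counts.individual == "s1"]
    # one specific locus collects (3, 1); the mismatching read counts nowhere
    assert (locus.groupby(["contig", "pos"])[["count_a", "count_b"]].sum().max(axis=1) <= 3).all()
    best = locus.sort_values("count_a", ascending=False).iloc[0]
    assert best.count_a == 3 and best.count_b == 1


def test_count_alleles_reverse_complement_hits(toy_locus):
    from gbsmap.kmers import revcomp

    a, b, m, placed, k = toy_locus
    a_kmer = m[m.parent == "A"].kmer.iloc[0]
    counts = count_alleles({"s1": [revcomp(a_kmer)]}, placed, m, k)
    assert counts.count_a.sum() >= 1


@pytest.mark.parametrize(
    "ca,cb,expected",
    [
        (5, 0, "AA"),
        (0, 5, "BB"),
        (3, 4, "AB"),
        (1, 1, "AB"),
        (1, 0, "NA"),
        (0, 0, "NA"),
        (2, 0, "AA"),
    ],
)
def test_call_genotype_rules(ca, cb, expected):
    frame = pd.DataFrame(
        {"individual": ["x"], "contig": ["c"], "pos": [0], "count_a": [ca], "count_b": [cb]}
    )
    assert call_genotypes(frame, min_allele=2).call.iloc[0] == expected


# -- consensus binning -----------------------------------------------------


def _calls(rows):
    return pd.DataFrame(rows, columns=["individual", "contig", "pos", "call"]).assign(
        count_a=0, count_b=0
    )


def test_bin_majority_example():
    calls = _calls(
        [("i1", "c", 10, "AA"), ("i1", "c", 20, "AA"), ("i1", "c", 30, "AA"), ("i1", "c", 40, "AB")]
    )
    mat = bin_consensus(calls, {"c": 14_000}, min_calls=2)
    assert CODE_LETTERS[mat.codes[0, 0]] == "A"


def test_bin_tie_gives_unknown():
    calls = _calls(
        [("i1", "c", 1, "AA"), ("i1", "c", 2, "AA"), ("i1", "c", 3, "BB"), ("i1", "c", 4, "BB")]
    )
    mat = bin_consensus(calls, {"c": 14_000}, min_calls=2)
    assert CODE_LETTERS[mat.codes[0, 0]] == "U"


def test_bin_window_tiling_truncates_terminal_window():
    mat = bin_consensus(_calls([("i1", "c", 0, "AA")]), {"c": 30_000}, min_calls=1)
    assert list(mat.loci.start) == [0, 14_000, 28_000]
    assert list(mat.loci.end) == [14_000, 28_000, 30_000]


def test_bin_min_calls_threshold():
    calls = _calls([("i1", "c", 1, "AA")])
    assert CODE_LETTERS[bin_consensus(calls, {"c": 100}, min_calls=2).codes[0, 0]] == "U"
    assert CODE_LETTERS[bin_consensus(calls, {"c": 100}, min_calls=1).codes[0, 0]] == "A"


def test_bin_unknown_individual_raises():
    with pytest.raises(KeyError, match="unknown individuals"):
        bin_consensus(_calls([("ghost", "c", 0, "AA")]), {"c": 100}, individuals=["i1"])


def _brute_force_bin(calls, lengths, window, min_calls, individuals):
    out = {}
    for contig, L in lengths.items():
        n_w = max(1, -(-L // window))
        for w in range(n_w):
            for ind in individuals:
                sub = calls[
                    (calls.contig == contig)
                    & (calls.individual == ind)
                    & (calls.pos >= w * window)
                    & (calls.pos < (w + 1) * window)
                    & calls.call.isin(["AA", "AB", "BB"])
                ]
                tally = sub.call.value_counts()
                if tally.empty:
                    out[(contig, w, ind)] = "U"
                    continue
                best = tally.idxmax()
                rivals = tally.drop(best)
                if tally[best] >= min_calls and (rivals.empty or tally[best] > rivals.max()):
                    out[(contig, w, ind)] = {"AA": "A", "AB": "H", "BB": "B"}[best]
                else:
                    out[(contig, w, ind)] = "U"
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_bin_matches_brute_force_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    individuals = [f"i{j}" for j in range(4)]
    lengths = {"cA": 30_000, "cB": 9_000}
    n = 120
    calls = pd.DataFrame(
        {
            "individual": rng.choice(individuals, n),
            "contig": rng.choice(list(lengths), n),
            "pos": rng.integers(0, 30_000, n),
            "call": rng.choice(["AA", "AB", "BB", "NA"], n),
        }
    )
    calls = calls[calls.pos < calls.contig.map(lengths)].reset_index(drop=True)
    mat = bin_consensus(calls, lengths, min_calls=2, individuals=individuals)
    expect = _brute_force_bin(calls, lengths, 14_000, 2, individuals)
    for li, row in mat.loci.iterrows():
        for ii, ind in enumerate(individuals):
            assert CODE_LETTERS[mat.codes[li, ii]] == expect[(row.contig, row.window_index, ind)]


def test_matrix_tsv_round_trip(tmp_path):
    loci = pd.DataFrame(
        {"contig": ["c", "c"], "window_index": [0, 1], "start": [0, 14000], "end": [14000, 20000]}
    )
    codes = np.array([[0, 1], [3, 2]], dtype=np.uint8)
    mat = GenotypeMatrix(loci=loci, individuals=["i1", "i2"], codes=codes)
    p = tmp_path / "m.tsv"
    mat.write_tsv(p)
    frame = pd.read_csv(p, sep="\t", index_col=0)
    back = GenotypeMatrix.from_frame(frame, loci)
    assert np.array_equal(back.codes, codes)


def test_end_to_end_consensus_matches_truth_without_crossovers(tmp_path):
    """Error-free reads at high depth: consensus equals truth at every
    informative window (no crossover ambiguity with crossover_mean=0)."""
    from gbsmap.evaluate import evaluate_against_truth
    from gbsmap.simulate import (
        SimConfig,
        fragment_reference,
        simulate_f2_population,
        simulate_gbs_run,
        simulate_parents,
    )

    cfg = SimConfig(
        n_chromosomes=1,
        chromosome_length=60_000,
        snv_rate=0.004,
        n_individuals=12,
        crossover_mean=0.0,
        mean_depth=10.0,
        n_contigs=3,
        min_contig_length=5_000,
        seed=13,
    )
    truth = simulate_parents(cfg)
    simulate_f2_population(truth, cfg)
    contigs, _, _ = fragment_reference(truth, cfg, chimeras=[])
    fq = tmp_path / "r.fastq"
    simulate_gbs_run(truth, cfg, fq)
    k = 51
    m = discover_markers(
        count_kmers(list(truth.haplotype_a.values()), k),
        count_kmers(list(truth.haplotype_b.values()), k),
    )
    placed, _ = place_markers(m, contigs)
    res = demultiplex(str(fq), cfg.barcodes, outdir=str(tmp_path / "demux"))
    reads = {s: p for s, p in res.paths.items() if s != "unassigned"}
    calls = call_genotypes(count_alleles(reads, placed, m, k))
    mat = bin_consensus(
        calls, {n: len(s) for n, s in contigs.items()}, individuals=cfg.sample_ids
    )
    report = evaluate_against_truth(truth, consensus=mat)
    assert report["genotype_accuracy"] == 1.0
    assert report["n_calls"] > 0
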