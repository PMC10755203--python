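"""Misjoin detection, contig splitting, placement and AGP output."""

import numpy as np
import pandas as pd
import pytest

from gbsmap.genotyping import GenotypeMatrix
from gbsmap.kmers import revcomp
from gbsmap.scaffold import (
    build_pseudomolecules,
    detect_misjoins,
    orient_contig,
    order_contigs,
    place_contigs,
    rebuild_from_agp,
    relabel_loci_after_split,
    split_contigs,
    validate_agp,
)

W = 14_000


def _matrix(contig, window_codes):
    """Build a one-contig matrix from a (n_windows, n_ind) code array."""
    codes = np.asarray(window_codes, dtype=np.uint8)
    n_w = codes.shape[0]
    loci = pd.DataFrame(
        {
            "contig": contig,
            "window_index": np.arange(n_w),
            "start": np.arange(n_w) * W,
            "end": (np.arange(n_w) + 1) * W,
        }
    )
    return GenotypeMatrix(
        loci=loci, individuals=[f"i{j}" for j in range(codes.shape[1])], codes=codes
    )


def _f2_codes(rng, n):
    return rng.choice([0, 1, 2], n, p=[0.25, 0.5, 0.25]).astype(np.uint8)


def test_chimeric_boundary_detected_with_expected_switch_fraction():
    rng = np.random.default_rng(0)
    n = 400
    left = _f2_codes(rng, n)
    right = _f2_codes(rng, n)  # unlinked: independent 1:2:1
    mat = _matrix("ctg", np.stack([left, left, right, right]))
    bps = detect_misjoins(mat, min_informative=20)
    assert len(bps) == 1
    assert bps.boundary_bp.iloc[0] == 2 * W
    # theoretical switch fraction for unlinked halves: 1 - (1/16 + 1/4 + 1/16)
    assert bps.switch_fraction.iloc[0] == pytest.approx(0.625, abs=0.06)


def test_clean_contig_has_no_breakpoints():
    rng = np.random.default_rng(1)
    base = _f2_codes(rng, 300)
    windows = []
    for _ in range(6):
        drift = base.copy()
        flip = rng.random(300) < 0.03  # light local recombination
        drift[flip] = rng.choice([0, 1, 2], int(flip.sum()))
        windows.append(drift)
        base = drift
    assert detect_misjoins(_matrix("ctg", np.stack(windows))).empty


def test_low_informative_boundary_suppressed():
    rng = np.random.default_rng(2)
    left = _f2_codes(rng, 30)
    right = _f2_codes(rng, 30)
    left[5:] = 3  # only 5 informative individuals
    mat = _matrix("ctg", np.stack([left, right]))
    assert detect_misjoins(mat, min_informative=20).empty


def test_distorted_window_does_not_trigger_breakpoint():
    # allele-specific dropout: one window nearly all-A, neighbour normal
    rng = np.random.default_rng(3)
    normal = _f2_codes(rng, 300)
    dropout = np.where(normal == 1, 0, normal).astype(np.uint8)  # H read as A
    mat = _matrix("ctg", np.stack([normal, dropout]))
    assert detect_misjoins(mat).empty


def test_single_window_contig_yields_nothing():
    rng = np.random.default_rng(4)
    mat = _matrix("ctg", _f2_codes(rng, 50)[None, :])
    assert detect_misjoins(mat).empty


def test_adjacent_qualifying_boundaries_merge_to_max():
    rng = np.random.default_rng(5)
    n = 400
    a = _f2_codes(rng, n)
    mixed = np.where(rng.random(n) < 0.5, a, _f2_codes(rng, n)).astype(np.uint8)
    b = _f2_codes(rng, n)
    mat = _matrix("ctg", np.stack([a, a, mixed, b, b]))
    bps = detect_misjoins(mat, min_switch=0.3)
    assert len(bps) == 1


# -- splitting -------------------------------------------------------------


def test_split_lengths_and_round_trip():
    seq = "ACGT" * 30_000  # 120 kb
    bps = pd.DataFrame({"contig": ["c1"], "boundary_bp": [70_000]})
    out, prov = split_contigs({"c1": seq}, bps, window=14_000)
    assert set(out) == {"c1.1", "c1.2"}
    assert len(out["c1.1"]) == 70_000 and len(out["c1.2"]) == 50_000
    assert out["c1.1"] + out["c1.2"] == seq
    assert prov.loc[prov.part == "c1.2", "start"].iloc[0] == 70_000


def test_split_no_breakpoints_is_identity():
    contigs = {"a": "ACGTACGT", "b": "TTTT"}
    out, prov = split_contigs(contigs, pd.DataFrame(columns=["contig", "boundary_bp"]))
    assert out == contigs
    assert set(prov.part) == {"a", "b"}


def test_split_rejects_off_boundary_breakpoint():
    with pytest.raises(ValueError, match="window boundary"):
        split_contigs(
            {"c": "A" * 50_000},
            pd.DataFrame({"contig": ["c"], "boundary_bp": [13_999]}),
            window=14_000,
        )


def test_relabel_loci_after_split_shifts_windows():
    loci = pd.DataFrame(
        {
            "contig": ["c", "c", "c"],
            "window_index": [0, 1, 2],
            "start": [0, W, 2 * W],
            "end": [W, 2 * W, 2 * W + 5_000],
        }
    )
    prov = pd.DataFrame(
        {
            "part": ["c.1", "c.2"],
            "source_contig": ["c", "c"],
            "start": [0, W],
            "end": [W, 2 * W + 5_000],
        }
    )
    new = relabel_loci_after_split(loci, prov)
    assert list(new.contig) == ["c.1", "c.2", "c.2"]
    assert list(new.start) == [0, 0, W]
    assert list(new.window_index) == [0, 0, 1]


# -- placement -------------------------------------------------------------


def _locus_map(rows):
    return pd.DataFrame(
        rows,
        columns=["group", "order_index", "contig", "window_index", "position_cm", "locus_index", "start", "end"],
    )


def test_place_contigs_majority_conflict_and_unplaced():
    lm = _locus_map(
        [
            ("LG01", 0, "p1", 0, 0.0, 0, 0, W),
            ("LG01", 1, "p1", 1, 5.0, 1, W, 2 * W),
            ("LG02", 0, "p2", 0, 0.0, 2, 0, W),
            ("LG01", 2, "p2", 1, 9.0, 3, W, 2 * W),
            ("LG01", 3, "p2", 2, 12.0, 4, 2 * W, 3 * W),
        ]
    )
    placements = place_contigs(lm, ["p1", "p2", "p3"])
    p1 = placements[placements.part == "p1"].iloc[0]
    p2 = placements[placements.part == "p2"].iloc[0]
    p3 = placements[placements.part == "p3"].iloc[0]
    assert p1.group == "LG01" and not p1.conflict
    assert p2.group == "LG01" and p2.conflict
    assert pd.isna(p3.group)


@pytest.mark.parametrize(
    "cm,expected",
    [
        ([0.0, 5.0, 9.0], "+"),
        ([9.0, 5.0, 0.0], "-"),
        ([4.0], "?"),
        ([3.0, 3.0, 3.0], "?"),
    ],
)
def test_orient_contig(cm, expected):
    mids = np.arange(len(cm)) * W + W / 2
    assert orient_contig(mids, np.array(cm)) == expected


def test_order_contigs_ties_break_lexicographically():
    placements = pd.DataFrame(
        {
            "part": ["b", "a", "c"],
            "group": ["LG01", "LG01", "LG01"],
            "position_cm": [5.0, 5.0, 1.0],
            "orientation": ["+", "+", "+"],
        }
    )
    out = order_contigs(placements).set_index("part")["order_index"]
    assert out["c"] == 0 and out["a"] == 1 and out["b"] == 2


def test_empty_group_gives_empty_order():
    out = order_contigs(
        pd.DataFrame(columns=["part", "group", "position_cm", "orientation"])
    )
    assert out.empty


# -- pseudomolecules and AGP ----------------------------------------------


@pytest.fixture()
def toy_placements():
    return pd.DataFrame(
        {
            "part": ["p1", "p2", "p3"],
            "group": ["LG01", "LG01", None],
            "position_cm": [0.0, 8.0, np.nan],
            "orientation": ["+", "-", "?"],
            "order_index": [0, 1, -1],
        }
    )


@pytest.fixture()
def toy_contigs():
    rng = np.random.default_rng(6)
    return {
        n: "".join("ACGT"[i] for i in rng.integers(0, 4, ln))
        for n, ln in [("p1", 500), ("p2", 300), ("p3", 120)]
    }


def test_build_pseudomolecules_layout(toy_placements, toy_contigs):
    pseudos, agp, unplaced = build_pseudomolecules(toy_placements, toy_contigs, gap=100)
    assert list(pseudos) == ["pseudo_01"]
    seq = pseudos["pseudo_01"]
    assert len(seq) == 500 + 100 + 300
    assert seq[:500] == toy_contigs["p1"]
    assert seq[500:600] == "N" * 100
    assert seq[600:] == revcomp(toy_contigs["p2"])  # '-' part reverse-complemented
    w_rows = agp[(agp.object == "pseudo_01")]
    assert len(w_rows) == 3  # W, U, W
    assert list(w_rows.component_type) == ["W", "U", "W"]
    assert "scaffold_p3" in unplaced


def test_agp_validates_and_rebuilds(toy_placements, toy_contigs):
    pseudos, agp, unplaced = build_pseudomolecules(toy_placements, toy_contigs)
    validate_agp(agp, {n: len(s) for n, s in toy_contigs.items()})
    rebuilt = rebuild_from_agp(agp, toy_contigs)
    for name, seq in pseudos.items():
        assert rebuilt[name] == seq
    for name, seq in unplaced.items():
        assert rebuilt[name] == seq


def test_validate_agp_rejects_corruption(toy_placements, toy_contigs):
    _, agp, _ = build_pseudomolecules(toy_placements, toy_contigs)
    bad = agp.copy()
    bad.loc[bad.index[1], "object_beg"] += 1
    with pytest.raises(ValueError):
        validate_agp(bad)
    bad2 = agp.copy()
    bad2.loc[bad2.component_type == "W", "component_end"] += 5
    with pytest.raises(ValueError):
        validate_agp(bad2, {n: len(s) for n, s in toy_contigs.items()})


def test_missing_part_sequence_raises(toy_placements):
    with pytest.raises(KeyError, match="p2"):
        build_pseudomolecules(toy_placements, {"p1": "ACGT", "p3": "ACGT"})
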