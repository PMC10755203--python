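"""Misjoin detection and genetic-map-guided scaffolding.

A chimeric contig joins sequence from two unlinked regions; in an F2
population nearly every individual then appears to switch genotype at the
junction (the expected switch fraction for unlinked halves is
1 - (1/4^2 + 1/2^2 + 1/4^2) = 0.625, versus roughly the per-window
recombination fraction for genuinely adjacent windows).  Detected junctions
are broken at window boundaries, parts are assigned to linkage groups,
oriented by the bp-vs-cM trend of their windows, ordered by median map
position, and joined into pseudomolecules with 100-N gaps plus an AGP v2.1
layout from which the FASTA is bit-exactly reconstructable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .genotyping import GenotypeMatrix, U
from .kmers import revcomp
from .linkmap import GeneticMap

__all__ = [
    "Breakpoint",
    "detect_misjoins",
    "split_contigs",
    "relabel_loci_after_split",
    "locus_map_frame",
    "assign_contigs",
    "orient_contig",
    "order_contigs",
    "place_contigs",
    "build_pseudomolecules",
    "validate_agp",
    "rebuild_from_agp",
]


@dataclass(frozen=True)
class Breakpoint:
    """A population-wide haplotype switch at a window boundary."""

    contig: str
    boundary_bp: int
    switch_fraction: float
    n_informative: int


def detect_misjoins(
    matrix: GenotypeMatrix,
    min_switch: float = 0.5,
    min_informative: int = 20,
    distortion_alpha: float = 1e-6,
) -> pd.DataFrame:
    """Scan each contig's window track for simultaneous haplotype switches.

    For every adjacent window boundary, over individuals informative (non-U)
    in both windows, the switch fraction is the fraction whose genotype
    differs.  Boundaries with switch_fraction >= ``min_switch`` and at least
    ``min_informative`` informative individuals qualify; runs of adjacent
    qualifying boundaries are merged to the single maximum-fraction boundary.
    Contigs with fewer than two windows yield nothing.

    Unusable windows are removed from the track before boundary analysis, so
    a junction is judged between the nearest usable windows and reported at
    the boundary of the left one.  Two kinds are removed: windows with fewer
    than ``min_informative`` genotyped individuals (e.g. no sequenced
    fragment ends — they would silence both their boundaries), and windows
    grossly violating F2 segregation (chi-square against 1:2:1,
    p < ``distortion_alpha``): allele-specific dropout, typically an SNV
    inside a restriction site silencing one haplotype's fragments, distorts
    a window's genotypes in a way that both mimics and masks population-wide
    switches, whereas a genuine window always segregates 1:2:1.  The switch
    fraction between genuinely linked windows a few windows apart is still
    far below ``min_switch``, so skipping windows does not create false
    positives.
    """
    from .linkmap import segregation_pvalues

    pvals = segregation_pvalues(matrix)
    informative_n = (matrix.codes != U).sum(axis=1)
    rows = []
    loci = matrix.loci
    for contig, sub in loci.groupby("contig", sort=False):
        sub = sub.sort_values("start")
        idx = sub.index.to_numpy()
        idx = idx[(pvals[idx] >= distortion_alpha) & (informative_n[idx] >= min_informative)]
        if idx.size < 2:
            continue
        sub = loci.loc[idx]
        codes = matrix.codes[idx]
        left, right = codes[:-1], codes[1:]
        inf = (left != U) & (right != U)
        n_inf = inf.sum(axis=1)
        with np.errstate(invalid="ignore"):
            frac = np.where(n_inf > 0, ((left != right) & inf).sum(axis=1) / np.maximum(n_inf, 1), 0.0)
        qual = (frac >= min_switch) & (n_inf >= min_informative)
        boundaries = sub["end"].to_numpy()[:-1]
        # merge runs of adjacent qualifying boundaries to the max-fraction one
        i = 0
        while i < qual.size:
            if not qual[i]:
                i += 1
                continue
            j = i
            while j + 1 < qual.size and qual[j + 1]:
                j += 1
            k = i + int(np.argmax(frac[i : j + 1]))
            rows.append((contig, int(boundaries[k]), float(frac[k]), int(n_inf[k])))
            i = j + 1
    return pd.DataFrame(rows, columns=["contig", "boundary_bp", "switch_fraction", "n_informative"])


def split_contigs(
    contigs: dict[str, str],
    breakpoints: pd.DataFrame,
    window: int = 14_000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Break contigs at detected boundaries.

    Parts are named ``<contig>.1``, ``<contig>.2``, ... and concatenate back
    to the original sequence.  Returns the revised contig dict and a
    provenance table (``part, source_contig, start, end``).  Breakpoints must
    lie on window-tiling boundaries (multiples of ``window``).
    """
    bp_of: dict[str, list[int]] = {}
    for _, row in breakpoints.iterrows():
        c, b = row["contig"], int(row["boundary_bp"])
        if c not in contigs:
            raise KeyError(f"breakpoint names unknown contig {c!r}")
        if not 0 < b < len(contigs[c]):
            raise ValueError(f"breakpoint {b} outside contig {c} of length {len(contigs[c])}")
        if b % window != 0:
            raise ValueError(f"breakpoint {b} on {c} is not a window boundary (window={window})")
        bp_of.setdefault(c, []).append(b)

    out: dict[str, str] = {}
    prov_rows = []
    for name, seq in contigs.items():
        if name not in bp_of:
            out[name] = seq
            prov_rows.append((name, name, 0, len(seq)))
            continue
        bounds = [0] + sorted(set(bp_of[name])) + [len(seq)]
        for i in range(len(bounds) - 1):
            part = f"{name}.{i + 1}"
            out[part] = seq[bounds[i] : bounds[i + 1]]
            prov_rows.append((part, name, bounds[i], bounds[i + 1]))
    prov = pd.DataFrame(prov_rows, columns=["part", "source_contig", "start", "end"])
    return out, prov


def relabel_loci_after_split(loci: pd.DataFrame, provenance: pd.DataFrame) -> pd.DataFrame:
    """Rename window loci of split contigs to their parts.

    Because splits happen only at window boundaries, every window falls
    entirely inside one part; starts shift by the part offset and window
    indices are renumbered from the part start.  Row order is preserved, so
    genotype-matrix row indices (and any map built on them) stay valid.
    """
    pieces = provenance.sort_values(["source_contig", "start"])
    by_src: dict[str, list[tuple[int, int, str]]] = {}
    for _, row in pieces.iterrows():
        by_src.setdefault(row["source_contig"], []).append((int(row["start"]), int(row["end"]), row["part"]))
    new = loci.copy()
    width = None
    for i in new.index:
        c = new.at[i, "contig"]
        if c not in by_src:
            continue
        s, e = int(new.at[i, "start"]), int(new.at[i, "end"])
        for ps, pe, part in by_src[c]:
            if ps <= s and e <= pe:
                if width is None:
                    width = int((loci["end"] - loci["start"]).max())
                new.at[i, "contig"] = part
                new.at[i, "start"] = s - ps
                new.at[i, "end"] = e - ps
                new.at[i, "window_index"] = (s - ps) // max(width, 1)
                break
        else:
            raise ValueError(f"window [{s},{e}) of {c} does not fit inside any part")
    return new


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def locus_map_frame(genetic_map: GeneticMap, matrix: GenotypeMatrix) -> pd.DataFrame:
    """Join map positions onto window loci: one row per mapped locus with
    columns ``contig, window_index, start, end, group, position_cm,
    order_index``."""
    mp = genetic_map.to_frame(matrix.loci)
    loci = matrix.loci.reset_index().rename(columns={"index": "locus_index"})
    return mp.merge(loci[["locus_index", "start", "end"]], on="locus_index", how="left")


def assign_contigs(locus_map: pd.DataFrame, parts: list[str]) -> pd.DataFrame:
    """Assign each part to the linkage group holding the majority of its
    mapped windows; parts with windows in several groups are flagged as
    conflicts (candidate undetected chimeras); parts with no mapped windows
    go to the unplaced bin (group NA)."""
    rows = []
    grouped = locus_map.groupby("contig")["group"]
    for part in parts:
        if part in grouped.groups:
            vc = grouped.get_group(part).value_counts()
            rows.append((part, vc.idxmax(), int(vc.sum()), len(vc) > 1))
        else:
            rows.append((part, pd.NA, 0, False))
    return pd.DataFrame(rows, columns=["part", "group", "n_mapped", "conflict"])


def orient_contig(bp_mid: np.ndarray, cm: np.ndarray) -> str:
    """Orientation from the Kendall correlation of window bp midpoints with
    map positions: '+' if increasing, '-' if decreasing, '?' if undecidable
    (fewer than 2 distinct cM positions or zero correlation)."""
    if len(bp_mid) < 2 or len(np.unique(cm)) < 2:
        return "?"
    tau = kendalltau(bp_mid, cm).statistic
    if not np.isfinite(tau) or tau == 0:
        return "?"
    return "+" if tau > 0 else "-"


def order_contigs(placements: pd.DataFrame) -> pd.DataFrame:
    """Assign order indices within each group by median map position; ties
    break lexicographically by part id (deterministic)."""
    out = placements.copy()
    out["order_index"] = -1
    for grp, sub in out.dropna(subset=["group"]).groupby("group"):
        ordered = sub.sort_values(["position_cm", "part"]).index
        out.loc[ordered, "order_index"] = np.arange(len(ordered))
    return out


def place_contigs(locus_map: pd.DataFrame, parts: list[str]) -> pd.DataFrame:
    """Full placement table: group assignment, median cM position,
    orientation and order index per part."""
    assigned = assign_contigs(locus_map, parts)
    pos = []
    orient = []
    for _, row in assigned.iterrows():
        if pd.isna(row["group"]):
            pos.append(np.nan)
            orient.append("?")
            continue
        sub = locus_map[(locus_map["contig"] == row["part"]) & (locus_map["group"] == row["group"])]
        mid = ((sub["start"] + sub["end"]) / 2).to_numpy()
        cm = sub["position_cm"].to_numpy()
        pos.append(float(np.median(cm)))
        orient.append(orient_contig(mid, cm))
    assigned["position_cm"] = pos
    assigned["orientation"] = orient
    return order_contigs(assigned)


# ---------------------------------------------------------------------------
# pseudomolecules and AGP
# ---------------------------------------------------------------------------

_AGP_COLS = [
    "object",
    "object_beg",
    "object_end",
    "part_number",
    "component_type",
    "component_id",
    "component_beg",
    "component_end",
    "orientation",
]


def build_pseudomolecules(
    placements: pd.DataFrame,
    contigs: dict[str, str],
    gap: int = 100,
    name_prefix: str = "pseudo",
) -> tuple[dict[str, str], pd.DataFrame, dict[str, str]]:
    """Join ordered, oriented parts into pseudomolecules with N gaps.

    Per group, part sequences ('-' parts reverse-complemented, '?' treated as
    '+') are concatenated with ``gap`` Ns between them; the AGP v2.1 table
    alternates W components and U gap rows (gap_type "map", linkage "yes",
    evidence "map").  Unplaced parts are emitted as standalone scaffolds.
    Returns (pseudomolecules, agp, unplaced).
    """
    missing = [p for p in placements["part"] if p not in contigs]
    if missing:
        raise KeyError(f"part sequence missing for {missing[:5]}")
    pseudos: dict[str, str] = {}
    agp_rows = []
    groups = sorted(placements.dropna(subset=["group"])["group"].unique())
    for gi, grp in enumerate(groups):
        sub = placements[placements["group"] == grp].sort_values("order_index")
        obj = f"{name_prefix}_{gi + 1:02d}"
        pieces = []
        pos = 0
        part_no = 0
        for row_i, (_, row) in enumerate(sub.iterrows()):
            if row_i > 0:
                part_no += 1
                agp_rows.append(
                    (obj, pos + 1, pos + gap, part_no, "U", gap, "map", "yes", "map")
                )
                pieces.append("N" * gap)
                pos += gap
            seq = contigs[row["part"]]
            orient = row["orientation"] if row["orientation"] in ("+", "-") else "+"
            part_no += 1
            agp_rows.append(
                (obj, pos + 1, pos + len(seq), part_no, "W", row["part"], 1, len(seq), orient)
            )
            pieces.append(seq if orient == "+" else revcomp(seq))
            pos += len(seq)
        pseudos[obj] = "".join(pieces)

    unplaced: dict[str, str] = {}
    for _, row in placements[placements["group"].isna()].iterrows():
        part = row["part"]
        seq = contigs[part]
        obj = f"scaffold_{part}"
        unplaced[obj] = seq
        agp_rows.append((obj, 1, len(seq), 1, "W", part, 1, len(seq), "+"))
    agp = pd.DataFrame(agp_rows, columns=_AGP_COLS)
    return pseudos, agp, unplaced


def validate_agp(agp: pd.DataFrame, component_lengths: dict[str, int] | None = None) -> None:
    """Independent AGP v2.1 consistency check.

    Verifies 1-based inclusive coordinates, gap-free tiling of every object,
    consecutive part numbers, and (when component lengths are given) that W
    rows span their components exactly.  Raises ValueError on any violation.
    """
    for obj, sub in agp.groupby("object", sort=False):
        sub = sub.sort_values("part_number")
        expect_beg = 1
        for pn, (_, row) in enumerate(sub.iterrows(), start=1):
            if int(row["part_number"]) != pn:
                raise ValueError(f"{obj}: part numbers not consecutive at {pn}")
            beg, end = int(row["object_beg"]), int(row["object_end"])
            if beg != expect_beg:
                raise ValueError(f"{obj}: part {pn} starts at {beg}, expected {expect_beg}")
            if end < beg:
                raise ValueError(f"{obj}: part {pn} has end < beg")
            span = end - beg + 1
            if row["component_type"] == "U":
                if int(row["component_id"]) != span:
                    raise ValueError(f"{obj}: gap length mismatch at part {pn}")
            elif row["component_type"] == "W":
                cb, ce = int(row["component_beg"]), int(row["component_end"])
                if cb != 1 or ce - cb + 1 != span:
                    raise ValueError(f"{obj}: component span mismatch at part {pn}")
                if row["orientation"] not in ("+", "-"):
                    raise ValueError(f"{obj}: bad orientation {row['orientation']!r}")
                if component_lengths is not None:
                    L = component_lengths.get(row["component_id"])
                    if L is None:
                        raise ValueError(f"{obj}: unknown component {row['component_id']!r}")
                    if ce != L:
                        raise ValueError(
                            f"{obj}: component {row['component_id']} length {L} != span {ce}"
                        )
            else:
                raise ValueError(f"{obj}: unsupported component type {row['component_type']!r}")
            expect_beg = end + 1


def rebuild_from_agp(agp: pd.DataFrame, components: dict[str, str]) -> dict[str, str]:
    """Reconstruct object sequences from an AGP table and component dict."""
    out: dict[str, str] = {}
    for obj, sub in agp.groupby("object", sort=False):
        pieces = []
        for _, row in sub.sort_values("part_number").iterrows():
            if row["component_type"] == "U":
                pieces.append("N" * int(row["component_id"]))
            else:
                seq = components[row["component_id"]][
                    int(row["component_beg"]) - 1 : int(row["component_end"])
                ]
                pieces.append(seq if row["orientation"] == "+" else revcomp(seq))
        out[obj] = "".join(pieces)
    return out
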