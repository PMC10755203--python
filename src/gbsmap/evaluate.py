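"""Scoring pipeline outputs against the simulator's ground truth.

Metrics:

* genotype accuracy — fraction of non-missing consensus calls equal to the
  truth genotype (the majority truth genotype over the SNVs inside each
  window, per individual);
* per-linkage-group |Kendall tau| between the inferred locus order and the
  true bp order (absolute value: a map is defined only up to reversal);
* breakpoint recall/precision against planted chimera junctions with a
  +/- one-window tolerance;
* contig order |tau| and orientation accuracy per group, after fixing each
  group's free polarity by the sign of its order correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .genotyping import GenotypeMatrix, U
from .simulate import TruthSet

__all__ = ["evaluate_against_truth", "truth_window_genotypes"]


def _layout_segments(truth: TruthSet, provenance: pd.DataFrame | None):
    """Per assembly part: list of (part_start, part_end, chromosome,
    chrom_start, chrom_end).  Provenance maps split parts back to their
    source contigs."""
    lay = truth.contig_layout
    if lay is None:
        raise ValueError("truth has no contig layout")
    segs: dict[str, list[tuple[int, int, str, int, int]]] = {}
    for contig, sub in lay.groupby("contig", sort=False):
        off = 0
        entries = []
        for _, row in sub.sort_values("part_index").iterrows():
            ln = int(row["end"] - row["start"])
            entries.append((off, off + ln, row["chromosome"], int(row["start"]), int(row["end"])))
            off += ln
        segs[contig] = entries
    if provenance is not None:
        out: dict[str, list[tuple[int, int, str, int, int]]] = {}
        for _, row in provenance.iterrows():
            part, src = row["part"], row["source_contig"]
            ps, pe = int(row["start"]), int(row["end"])
            if src not in segs:
                raise KeyError(f"provenance references unknown contig {src!r}")
            entries = []
            for s, e, chrom, cs, ce in segs[src]:
                lo, hi = max(s, ps), min(e, pe)
                if lo < hi:
                    entries.append((lo - ps, hi - ps, chrom, cs + (lo - s), cs + (hi - s)))
            out[part] = entries
        segs = out
    return segs


def _window_truth_region(segs, contig: str, start: int, end: int):
    """Chromosomal intervals covered by a window of an assembly part."""
    if contig not in segs:
        raise KeyError(f"window references unknown contig {contig!r}")
    regions = []
    for s, e, chrom, cs, _ce in segs[contig]:
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            regions.append((chrom, cs + (lo - s), cs + (hi - s)))
    return regions


def truth_window_genotypes(
    truth: TruthSet,
    loci: pd.DataFrame,
    individuals: list[str],
    provenance: pd.DataFrame | None = None,
) -> np.ndarray:
    """Majority truth genotype codes (0=A,1=H,2=B,3=U) per window locus per
    individual, derived from the gamete mosaics at the SNVs in each window.
    Windows with no SNVs are U."""
    segs = _layout_segments(truth, provenance)
    n_ind = len(individuals)
    ind_pos = {s: i for i, s in enumerate(individuals)}
    missing = set(individuals) - set(truth.individuals)
    if missing:
        raise KeyError(f"individuals unknown to the truth set: {sorted(missing)[:5]}")
    out = np.full((len(loci), n_ind), U, dtype=np.uint8)
    # gather per-chromosome dosage once
    by_chrom: dict[str, tuple[np.ndarray, pd.DataFrame]] = {}
    for chrom in truth.haplotype_a:
        pos, _a, _b = truth.snv_arrays(chrom)
        if pos.size:
            by_chrom[chrom] = (pos, truth.genotype_dosage(chrom, pos)[individuals].to_numpy())
    for li, row in enumerate(loci.itertuples(index=False)):
        votes = np.zeros((n_ind, 3), dtype=np.int64)
        for chrom, cs, ce in _window_truth_region(segs, row.contig, int(row.start), int(row.end)):
            if chrom not in by_chrom:
                continue
            pos, dos = by_chrom[chrom]
            i0, i1 = np.searchsorted(pos, [cs, ce])
            if i0 == i1:
                continue
            sub = dos[i0:i1]  # (n_snv, n_ind) dose of B
            for g in range(3):
                votes[:, g] += (sub == g).sum(axis=0)
        tot = votes.sum(axis=1)
        best = votes.argmax(axis=1)
        best_n = votes.max(axis=1)
        second = np.sort(votes, axis=1)[:, 1]
        code = np.where((tot > 0) & (best_n > second), best, U)
        out[li] = code
    return out


def evaluate_against_truth(
    truth: TruthSet,
    consensus: GenotypeMatrix | None = None,
    genetic_map=None,
    breakpoints: pd.DataFrame | None = None,
    placements: pd.DataFrame | None = None,
    provenance: pd.DataFrame | None = None,
    window: int = 14_000,
) -> dict:
    """Score any subset of pipeline outputs against the truth set.

    Returns a dict with keys among ``genotype_accuracy``, ``order_tau`` (per
    group and mean), ``breakpoint_recall``, ``breakpoint_precision``,
    ``orientation_accuracy`` and ``contig_order_tau``.
    """
    report: dict = {}
    segs = _layout_segments(truth, provenance) if (
        consensus is not None or genetic_map is not None or placements is not None
    ) else None

    if consensus is not None:
        truth_codes = truth_window_genotypes(truth, consensus.loci, consensus.individuals, provenance)
        called = consensus.codes != U
        comparable = called & (truth_codes != U)
        n_called = int(called.sum())
        n_ok = int((consensus.codes == truth_codes)[comparable].sum())
        report["genotype_accuracy"] = n_ok / max(int(comparable.sum()), 1)
        report["n_calls"] = n_called

    if genetic_map is not None and consensus is not None:
        taus = {}
        for grp in genetic_map.groups:
            if len(grp) < 3:
                continue
            rows = consensus.loci.iloc[grp.loci]
            chroms, mids = [], []
            for row in rows.itertuples(index=False):
                regions = _window_truth_region(segs, row.contig, int(row.start), int(row.end))
                if not regions:
                    chroms.append(None)
                    mids.append(np.nan)
                    continue
                chrom, cs, ce = max(regions, key=lambda t: t[2] - t[1])
                chroms.append(chrom)
                mids.append((cs + ce) / 2)
            # score only the loci on the group's majority chromosome
            counts = pd.Series([c for c in chroms if c is not None]).value_counts()
            if counts.empty:
                continue
            major = counts.idxmax()
            ok = np.array([c == major for c in chroms])
            mids = np.asarray(mids, dtype=float)
            if ok.sum() < 3:
                continue
            tau = kendalltau(np.arange(len(grp))[ok], mids[ok]).statistic
            taus[grp.name] = abs(float(tau))
        report["order_tau"] = taus
        if taus:
            report["order_tau_mean"] = float(np.mean(list(taus.values())))

    if breakpoints is not None:
        truth_j = truth.chimera_truth if truth.chimera_truth is not None else pd.DataFrame(
            columns=["contig", "junction_offset"]
        )
        tol = window
        matched = set()
        hits = 0
        for _, det in breakpoints.iterrows():
            cand = truth_j[truth_j["contig"] == det["contig"]]
            got = False
            for ti, trow in cand.iterrows():
                if ti in matched:
                    continue
                if abs(int(det["boundary_bp"]) - int(trow["junction_offset"])) <= tol:
                    matched.add(ti)
                    got = True
                    break
            hits += got
        n_true = len(truth_j)
        n_det = len(breakpoints)
        report["breakpoint_recall"] = len(matched) / n_true if n_true else 1.0
        report["breakpoint_precision"] = hits / n_det if n_det else 1.0
        report["n_breakpoints_detected"] = n_det

    if placements is not None:
        placed = placements.dropna(subset=["group"]).copy()
        true_chrom = {}
        true_start = {}
        for part in placed["part"]:
            entries = segs.get(part)
            if not entries:
                continue
            main = max(entries, key=lambda t: t[1] - t[0])
            true_chrom[part] = main[2]
            true_start[part] = main[3]
        taus = []
        orient_ok = 0
        orient_n = 0
        for grp, sub in placed.groupby("group"):
            sub = sub[sub["part"].isin(true_start)].sort_values("order_index")
            if len(sub) < 2:
                continue
            ts = np.array([true_start[p] for p in sub["part"]], dtype=float)
            tau = kendalltau(np.arange(len(sub)), ts).statistic
            if np.isfinite(tau):
                taus.append(abs(float(tau)))
                expected = "+" if tau > 0 else "-"
                known = sub[sub["orientation"].isin(["+", "-"])]
                orient_ok += int((known["orientation"] == expected).sum())
                orient_n += len(known)
        if taus:
            report["contig_order_tau"] = float(np.mean(taus))
        if orient_n:
            report["orientation_accuracy"] = orient_ok / orient_n
    return report
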