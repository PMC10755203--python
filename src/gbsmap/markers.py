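"""Parent-diagnostic k-mer marker discovery and exact placement.

A diagnostic pair is two k-mers, one abundant in each inbred parent and absent
(or below a contamination ceiling) in the other, identical except at a single
SNV position.  Markers are plain sequences with a line tag; they acquire
coordinates only when placed on a draft assembly by exact, unique matching.

The default k is 51; tests use small odd k so brute-force oracles stay
tractable.  Count thresholds default to 1/0 when counting from genomes and
should be raised (e.g. ``min_count=3``) when counting from error-containing
reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmers import (
    KmerCounts,
    PackedIndex,
    decode_many,
    encode,
    mix64,
    pack_code_matrix,
    pack_windows,
    revcomp_packed,
    unpack_codes,
)

__all__ = [
    "KmerMarker",
    "PlacedMarker",
    "count_kmers",
    "discover_markers",
    "place_markers",
]


@dataclass(frozen=True)
class KmerMarker:
    """A parent-diagnostic k-mer (canonical form) with its allelic partner."""

    marker_id: str
    kmer: str
    parent_tag: str  # "A" or "B"
    partner_id: str
    count_self: int
    count_other: int


@dataclass(frozen=True)
class PlacedMarker:
    """A marker anchored at a unique exact match on the draft assembly."""

    marker_id: str
    contig: str
    start: int  # 0-based
    strand: str  # "+" or "-"
    snv_offset: int  # 0..k-1, in contig coordinates within the match


def count_kmers(sequences, k: int) -> KmerCounts:
    """Count canonical k-mers over reads or genome records.

    ``k`` must be odd (an even k-mer can equal its own reverse complement,
    making the canonical form ambiguous).  Windows containing N are skipped.
    """
    return KmerCounts.from_sequences(sequences, k)


def _kmer_column_codes(kmers: pd.Series | np.ndarray, k: int) -> np.ndarray:
    joined = "".join(kmers)
    arr = encode(joined)
    return arr.reshape(-1, k)


def _masked_keys(hi: np.ndarray, lo: np.ndarray, k: int) -> np.ndarray:
    """(n, k) matrix of 64-bit keys; entry (i, p) identifies k-mer i with
    position p wildcarded.  Exactness is re-verified by the caller."""
    h = (k + 1) // 2
    n = hi.size
    keys = np.empty((n, k), dtype=np.uint64)
    for p in range(k):
        if p < h:
            mhi = hi & ~np.uint64(3 << (2 * (h - 1 - p)))
            mlo = lo
        else:
            mhi = hi
            mlo = lo & ~np.uint64(3 << (2 * (k - 1 - p)))
        salt = np.uint64((p * 0x9E3779B97F4A7C15) % (1 << 64))
        keys[:, p] = mix64(mhi + salt, mlo)
    return keys


def discover_markers(
    counts_a: KmerCounts,
    counts_b: KmerCounts,
    min_count: int = 1,
    max_other: int = 0,
) -> pd.DataFrame:
    """Find all diagnostic k-mer pairs between two parental count tables.

    A k-mer x is A-diagnostic iff ``counts_a[x] >= min_count`` and
    ``counts_b[x] <= max_other``, and it has a partner y — a single-base
    substitution of x (in either orientation) — that is B-diagnostic by the
    symmetric rule.  All qualifying pairs are retained (one SNV can yield up
    to k pairs) and deduplicated by canonical pair.

    Returns a DataFrame with two rows per pair (parents A and B) and columns
    ``marker_id, kmer, parent, partner_id, count_self, count_other, pair_id,
    snv_pos`` where ``snv_pos`` is the differing position in the A-allele's
    canonical orientation.
    """
    if counts_a.k != counts_b.k:
        raise ValueError(f"count tables built with different k: {counts_a.k} vs {counts_b.k}")
    k = counts_a.k

    a_other = counts_b.lookup(counts_a.hi, counts_a.lo)
    a_sel = (counts_a.counts >= min_count) & (a_other <= max_other)
    a_hi, a_lo = counts_a.hi[a_sel], counts_a.lo[a_sel]
    a_self, a_oth = counts_a.counts[a_sel], a_other[a_sel]

    b_other = counts_a.lookup(counts_b.hi, counts_b.lo)
    b_sel = (counts_b.counts >= min_count) & (b_other <= max_other)
    b_hi, b_lo = counts_b.hi[b_sel], counts_b.lo[b_sel]
    b_self, b_oth = counts_b.counts[b_sel], b_other[b_sel]

    cols = [
        "marker_id",
        "kmer",
        "parent",
        "partner_id",
        "count_self",
        "count_other",
        "pair_id",
        "snv_pos",
        "b_flipped",
    ]
    if a_hi.size == 0 or b_hi.size == 0:
        return pd.DataFrame(columns=cols)

    # orient B candidates both ways so single-substitution matches against the
    # A-canonical orientation are found regardless of strand
    b_rhi, b_rlo = revcomp_packed(b_hi, b_lo, k)
    b2_hi = np.concatenate([b_hi, b_rhi])
    b2_lo = np.concatenate([b_lo, b_rlo])
    b2_src = np.concatenate([np.arange(b_hi.size), np.arange(b_hi.size)])

    a_keys = _masked_keys(a_hi, a_lo, k)  # (nA, k)
    b_keys = _masked_keys(b2_hi, b2_lo, k)  # (nB2, k)

    bk = b_keys.ravel()
    b_flat_idx = np.repeat(np.arange(b2_hi.size), k)
    order = np.argsort(bk, kind="stable")
    bk_s, b_flat_s = bk[order], b_flat_idx[order]
    # run-length index over equal sorted keys
    run_start = np.concatenate(([0], np.flatnonzero(bk_s[1:] != bk_s[:-1]) + 1))
    run_len = np.diff(np.append(run_start, bk_s.size))

    ak = a_keys.ravel()
    a_flat_idx = np.repeat(np.arange(a_hi.size), k)
    pos_flat = np.tile(np.arange(k), a_hi.size)
    # sort queries for cache-friendly binary search, then map back
    qorder = np.argsort(ak, kind="stable")
    aks = ak[qorder]
    left = np.searchsorted(bk_s, aks, side="left")
    has = (left < bk_s.size) & (bk_s[np.minimum(left, bk_s.size - 1)] == aks)
    run_id = np.searchsorted(run_start, left[has], side="right") - 1
    span = run_len[run_id]
    src = qorder[has]
    a_rep = np.repeat(a_flat_idx[src], span)
    p_rep = np.repeat(pos_flat[src], span)
    starts = np.repeat(left[has], span)
    if span.size:
        ends = np.cumsum(span)
        bump = np.arange(int(ends[-1])) - np.repeat(ends - span, span)
    else:
        bump = np.empty(0, dtype=np.int64)
    b_rep = b_flat_s[starts + bump]

    if a_rep.size == 0:
        return pd.DataFrame(columns=cols)

    # exact verification: the two k-mers must differ at exactly position p
    ca = unpack_codes(a_hi[a_rep], a_lo[a_rep], k)
    cb = unpack_codes(b2_hi[b_rep], b2_lo[b_rep], k)
    diff = ca != cb
    ok = (diff.sum(axis=1) == 1) & diff[np.arange(diff.shape[0]), p_rep]
    a_rep, b_rep, p_rep = a_rep[ok], b_rep[ok], p_rep[ok]
    b_orig = b2_src[b_rep]
    # True when the B allele's canonical form had to be reverse-complemented to
    # align with the A allele's canonical frame
    b_flip = b_rep >= b_hi.size

    # dedup by canonical (A-kmer, B-kmer) pair
    pair_key = a_rep.astype(np.int64) * np.int64(b_hi.size) + b_orig
    uniq, first = np.unique(pair_key, return_index=True)
    a_u, b_u, p_u, f_u = a_rep[first], b_orig[first], p_rep[first], b_flip[first]

    # deterministic ordering by packed A then B value
    ordu = np.lexsort((b_lo[b_u], b_hi[b_u], a_lo[a_u], a_hi[a_u]))
    a_u, b_u, p_u, f_u = a_u[ordu], b_u[ordu], p_u[ordu], f_u[ordu]

    n = a_u.size
    a_strs = decode_many(a_hi[a_u], a_lo[a_u], k)
    b_strs = decode_many(b_hi[b_u], b_lo[b_u], k)
    width = max(6, len(str(n)))
    ida = np.array([f"A{i + 1:0{width}d}" for i in range(n)])
    idb = np.array([f"B{i + 1:0{width}d}" for i in range(n)])
    frame = pd.DataFrame(
        {
            "marker_id": np.concatenate([ida, idb]),
            "kmer": np.concatenate([a_strs, b_strs]).astype(str),
            "parent": ["A"] * n + ["B"] * n,
            "partner_id": np.concatenate([idb, ida]),
            "count_self": np.concatenate([a_self[a_u], b_self[b_u]]),
            "count_other": np.concatenate([a_oth[a_u], b_oth[b_u]]),
            "pair_id": np.concatenate([np.arange(n), np.arange(n)]),
            "snv_pos": np.concatenate([p_u, p_u]),
            "b_flipped": np.concatenate([f_u, f_u]),
        }
    )
    return frame.sort_values(["pair_id", "parent"], ignore_index=True)


def _assembly_windows(contigs: dict[str, str], k: int):
    names = list(contigs)
    hi_parts, lo_parts, ctg_parts, pos_parts = [], [], [], []
    for ci, name in enumerate(names):
        codes = encode(contigs[name])
        hi, lo, valid = pack_windows(codes, k)
        idx = np.flatnonzero(valid)
        hi_parts.append(hi[idx])
        lo_parts.append(lo[idx])
        pos_parts.append(idx)
        ctg_parts.append(np.full(idx.size, ci, dtype=np.int32))
    if not hi_parts:
        z = np.empty(0, dtype=np.uint64)
        return names, z, z.copy(), np.empty(0, np.int32), np.empty(0, np.int64)
    return (
        names,
        np.concatenate(hi_parts),
        np.concatenate(lo_parts),
        np.concatenate(ctg_parts),
        np.concatenate(pos_parts).astype(np.int64),
    )


def place_markers(markers: pd.DataFrame, contigs: dict[str, str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place diagnostic markers on a draft assembly by exact unique match.

    A marker is placed iff its k-mer (or its reverse complement) occurs exactly
    once across all contigs.  Because the assembly derives from parent A, a
    pair is anchored by whichever allele matches (normally A); the partner
    inherits the same locus.  Pairs with zero or multiple assembly hits, or
    with both alleles present, are rejected with a reason.

    Returns ``(placed, rejected)``: ``placed`` has one row per marker with
    ``marker_id, pair_id, parent, contig, start, strand, snv_offset``;
    ``rejected`` has ``marker_id, reason``.
    """
    if markers.empty:
        return (
            pd.DataFrame(
                columns=["marker_id", "pair_id", "parent", "contig", "start", "strand", "snv_offset"]
            ),
            pd.DataFrame(columns=["marker_id", "reason"]),
        )
    k = len(markers["kmer"].iat[0])
    codes = _kmer_column_codes(markers["kmer"].to_numpy(), k)
    m_hi, m_lo = pack_code_matrix(codes)
    r_hi, r_lo = revcomp_packed(m_hi, m_lo, k)

    n_m = m_hi.size
    key_hi = np.concatenate([m_hi, r_hi])
    key_lo = np.concatenate([m_lo, r_lo])
    key_marker = np.concatenate([np.arange(n_m), np.arange(n_m)])
    key_strand = np.concatenate([np.zeros(n_m, np.int8), np.ones(n_m, np.int8)])
    index = PackedIndex(key_hi, key_lo)

    names, w_hi, w_lo, w_ctg, w_pos = _assembly_windows(contigs, k)
    found = index.find(w_hi, w_lo)
    hit = found >= 0
    hit_entry = found[hit]
    hit_marker = key_marker[hit_entry]
    hit_strand = key_strand[hit_entry]
    hit_ctg = w_ctg[hit]
    hit_pos = w_pos[hit]

    occ = np.bincount(hit_marker, minlength=n_m)
    first_of = np.full(n_m, -1, dtype=np.int64)
    uniq_m, first_idx = np.unique(hit_marker, return_index=True)
    first_of[uniq_m] = first_idx

    # pair-wise resolution, vectorised over pairs.  After discover_markers'
    # sort the frame holds the A row then the B row of each pair.
    m = markers.reset_index(drop=True)
    a_rows = np.flatnonzero((m["parent"] == "A").to_numpy())
    b_rows = np.flatnonzero((m["parent"] == "B").to_numpy())
    a_rows = a_rows[np.argsort(m["pair_id"].to_numpy()[a_rows], kind="stable")]
    b_rows = b_rows[np.argsort(m["pair_id"].to_numpy()[b_rows], kind="stable")]
    occ_a, occ_b = occ[a_rows], occ[b_rows]

    multi = (occ_a > 1) | (occ_b > 1)
    both = ~multi & (occ_a == 1) & (occ_b == 1)
    nohit = (occ_a == 0) & (occ_b == 0)
    ok_pair = ~multi & ~both & ~nohit

    marker_ids = m["marker_id"].to_numpy()
    rej_reason = np.where(multi, "multi-mapping", np.where(both, "both-alleles-in-assembly", "no-hit"))
    rej_pairs = np.flatnonzero(~ok_pair)
    rejected = pd.DataFrame(
        {
            "marker_id": np.concatenate([marker_ids[a_rows[rej_pairs]], marker_ids[b_rows[rej_pairs]]]),
            "reason": np.concatenate([rej_reason[rej_pairs], rej_reason[rej_pairs]]),
        }
    )

    sel = np.flatnonzero(ok_pair)
    anchor_is_a = occ_a[sel] == 1
    anchor = np.where(anchor_is_a, a_rows[sel], b_rows[sel])
    e = first_of[anchor]
    ctg_idx = hit_ctg[e]
    start = hit_pos[e]
    strand_neg = hit_strand[e] == 1

    snv_pos = m["snv_pos"].to_numpy()[a_rows[sel]].astype(np.int64)
    b_flip = m["b_flipped"].to_numpy()[a_rows[sel]].astype(bool)
    # position of the SNV in the anchor allele's canonical frame
    pos_canon = np.where(anchor_is_a, snv_pos, np.where(b_flip, k - 1 - snv_pos, snv_pos))
    offset = np.where(strand_neg, k - 1 - pos_canon, pos_canon)

    name_arr = np.array(names, dtype=object)
    placed = pd.DataFrame(
        {
            "marker_id": np.concatenate([marker_ids[a_rows[sel]], marker_ids[b_rows[sel]]]),
            "pair_id": np.concatenate([m["pair_id"].to_numpy()[a_rows[sel]]] * 2),
            "parent": ["A"] * sel.size + ["B"] * sel.size,
            "contig": np.concatenate([name_arr[ctg_idx]] * 2),
            "start": np.concatenate([start] * 2),
            "strand": np.concatenate([np.where(strand_neg, "-", "+")] * 2),
            "snv_offset": np.concatenate([offset] * 2),
        }
    )
    if not placed.empty:
        placed = placed.sort_values(["contig", "start", "pair_id", "parent"], ignore_index=True)
    return placed, rejected
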