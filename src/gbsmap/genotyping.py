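"""GBS demultiplexing, diagnostic-allele counting and consensus binning.

Reads are assigned to samples by exact inline-barcode matching (longest
barcode first) requiring the ApeKI ``CWGC`` remnant immediately after the
barcode; the barcode is trimmed, the remnant retained.  Per-sample reads are
then scanned for exact occurrences of placed diagnostic k-mers, giving
per-locus parental allele counts, raw genotype calls, and finally
majority-rule consensus genotypes over fixed-width windows (default 14 kb)
tiling each contig.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .kmers import PackedIndex, encode, pack_code_matrix, pack_windows, revcomp_packed

__all__ = [
    "GenotypeMatrix",
    "demultiplex",
    "count_alleles",
    "count_pair_hits",
    "pair_counts_to_alleles",
    "call_genotypes",
    "bin_consensus",
    "CODE_LETTERS",
]

CODE_LETTERS = np.array(["A", "H", "B", "U"])
A, H, B, U = 0, 1, 2, 3

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "W": "AT", "S": "CG", "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "N": "ACGT",
}


def _remnant_set(remnant: str) -> set[str]:
    opts = [""]
    for ch in remnant:
        opts = [o + b for o in opts for b in _IUPAC[ch.upper()]]
    return set(opts)


def _norm_barcodes(barcodes) -> list[tuple[str, str]]:
    if isinstance(barcodes, pd.DataFrame):
        pairs = list(zip(barcodes.iloc[:, 0], barcodes.iloc[:, 1]))
    elif isinstance(barcodes, dict):
        pairs = list(barcodes.items())
    else:
        pairs = list(barcodes)
    seqs = [b for _, b in pairs]
    dup = {b for b in seqs if seqs.count(b) > 1}
    if dup:
        raise ValueError(f"duplicate barcode sequences: {sorted(dup)}")
    return pairs


@dataclass
class DemuxResult:
    """Outcome of demultiplexing one multiplexed FASTQ."""

    counts: pd.Series  # reads per sample (plus 'unassigned')
    paths: dict[str, str] | None = None  # per-sample FASTQ paths, if written
    reads: dict[str, list[tuple[str, str, str]]] | None = None  # in-memory mode

    @property
    def n_assigned(self) -> int:
        return int(self.counts.drop("unassigned").sum())


def demultiplex(
    fastq,
    barcodes,
    outdir: str | None = None,
    remnant: str = "CWGC",
    max_mismatch: int = 0,
) -> DemuxResult:
    """Split a multiplexed GBS FASTQ by inline barcode.

    A read is assigned to the unique sample whose barcode, immediately
    followed by a base string matching the remnant pattern, prefixes the read;
    barcodes are tried longest-first.  The barcode is trimmed and the remnant
    retained.  Everything else goes to ``unassigned``; assigned plus
    unassigned partition the input.  With ``outdir`` set, per-sample FASTQs
    are written; otherwise reads are returned in memory.
    """
    pairs = _norm_barcodes(barcodes)
    rset = _remnant_set(remnant)
    rlen = len(remnant)
    by_len: list[tuple[int, dict[str, str]]] = []
    for ln in sorted({len(b) for _, b in pairs}, reverse=True):
        by_len.append((ln, {b: s for s, b in pairs if len(b) == ln}))

    samples = [s for s, _ in pairs]
    counts = {s: 0 for s in samples}
    counts["unassigned"] = 0

    write_mode = outdir is not None
    if write_mode:
        os.makedirs(outdir, exist_ok=True)
        paths = {s: os.path.join(outdir, f"{s}.fastq") for s in samples}
        paths["unassigned"] = os.path.join(outdir, "unassigned.fastq")
        handles = {s: open(p, "w") for s, p in paths.items()}
        buffers: dict[str, list[str]] = {s: [] for s in paths}
    else:
        reads: dict[str, list[tuple[str, str, str]]] = {s: [] for s in samples}
        reads["unassigned"] = []

    def assign(seq: str) -> tuple[str | None, int]:
        for ln, table in by_len:
            sample = table.get(seq[:ln])
            if sample is not None and seq[ln : ln + rlen] in rset:
                return sample, ln
        if max_mismatch > 0:
            best = None
            for s, b in pairs:
                ln = len(b)
                pre = seq[:ln]
                if len(pre) < ln:
                    continue
                mm = sum(x != y for x, y in zip(pre, b))
                if mm <= max_mismatch and seq[ln : ln + rlen] in rset:
                    if best is not None:
                        return None, 0  # ambiguous
                    best = (s, ln)
            if best:
                return best
        return None, 0

    close_handle = False
    if isinstance(fastq, (str, os.PathLike)):
        fh = open(fastq)
        close_handle = True
    else:
        fh = fastq
    try:
        for title, seq, qual in FastqGeneralIterator(fh):
            sample, ln = assign(seq)
            if sample is None:
                key, rec = "unassigned", (title, seq, qual)
            else:
                key, rec = sample, (title, seq[ln:], qual[ln:])
            counts[key] += 1
            if write_mode:
                buffers[key].append(f"@{rec[0]}\n{rec[1]}\n+\n{rec[2]}")
                if len(buffers[key]) >= 20_000:
                    handles[key].write("\n".join(buffers[key]) + "\n")
                    buffers[key].clear()
            else:
                reads[key].append(rec)
    finally:
        if close_handle:
            fh.close()
        if write_mode:
            for s, h in handles.items():
                if buffers[s]:
                    h.write("\n".join(buffers[s]) + "\n")
                h.close()

    series = pd.Series(counts, name="n_reads")
    if write_mode:
        return DemuxResult(counts=series, paths=paths)
    return DemuxResult(counts=series, reads=reads)


# ---------------------------------------------------------------------------
# allele counting
# ---------------------------------------------------------------------------


class PairLookup:
    """Exact k-mer lookup from read windows to (diagnostic pair, parent).

    Indexes every marker allele in both orientations so scanning read windows
    on the forward strand alone is complete.  Counting per pair (rather than
    per placed locus) keeps the expensive read scan independent of any
    particular draft assembly; counts are projected onto placements
    afterwards.
    """

    def __init__(self, markers: pd.DataFrame, k: int):
        self.k = k
        m = markers.reset_index(drop=True)
        self.pair_ids = np.sort(m["pair_id"].unique())
        pair_pos = {p: i for i, p in enumerate(self.pair_ids)}
        pidx = m["pair_id"].map(pair_pos).to_numpy(dtype=np.int64)
        codes = encode("".join(m["kmer"])).reshape(-1, k)
        hi, lo = pack_code_matrix(codes)
        rhi, rlo = revcomp_packed(hi, lo, k)
        self._index = PackedIndex(np.concatenate([hi, rhi]), np.concatenate([lo, rlo]))
        parent_code = (m["parent"].to_numpy() == "B").astype(np.int8)
        self._pair = np.concatenate([pidx, pidx])
        self._parent = np.concatenate([parent_code, parent_code])

    @property
    def n_pairs(self) -> int:
        return self.pair_ids.size

    def count_sequences(self, seqs, chunk_bases: int = 8 << 20) -> np.ndarray:
        """Scan sequences; return (n_pairs, 2) counts of A/B allele hits."""
        out = np.zeros((self.n_pairs, 2), dtype=np.int64)
        buf: list[str] = []
        size = 0

        def flush():
            nonlocal buf, size
            if not buf:
                return
            codes = encode("N".join(buf))
            hi, lo, valid = pack_windows(codes, self.k)
            pos = self._index.find(hi[valid], lo[valid])
            entries = pos[pos >= 0]
            key = self._pair[entries] * 2 + self._parent[entries]
            out[:, :] += np.bincount(key, minlength=self.n_pairs * 2).reshape(-1, 2)
            buf, size = [], 0

        for s in seqs:
            if not s:
                continue
            buf.append(s)
            size += len(s) + 1
            if size >= chunk_bases:
                flush()
        flush()
        return out


def _iter_fastq_seqs(path: str):
    with open(path) as fh:
        for _t, seq, _q in FastqGeneralIterator(fh):
            yield seq


def count_pair_hits(reads_by_sample, markers: pd.DataFrame, k: int) -> pd.DataFrame:
    """Per-sample exact-match counts for every diagnostic pair.

    ``reads_by_sample`` maps sample id to a FASTQ path or an iterable of read
    sequences.  Returns one row per (sample, pair) with coverage:
    ``individual, pair_id, count_a, count_b``.
    """
    lookup = PairLookup(markers, k)
    frames = []
    for sample, src in reads_by_sample.items():
        seqs = _iter_fastq_seqs(src) if isinstance(src, (str, os.PathLike)) else iter(src)
        mat = lookup.count_sequences(seqs)
        nz = np.flatnonzero(mat.sum(axis=1))
        if nz.size == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "individual": sample,
                    "pair_id": lookup.pair_ids[nz],
                    "count_a": mat[nz, 0],
                    "count_b": mat[nz, 1],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["individual", "pair_id", "count_a", "count_b"])
    return pd.concat(frames, ignore_index=True)


def pair_counts_to_alleles(pair_counts: pd.DataFrame, placed: pd.DataFrame) -> pd.DataFrame:
    """Project pair-level counts onto the loci of one placed-marker set."""
    loci = placed[placed["parent"] == "A"][["pair_id", "contig", "start"]]
    out = pair_counts.merge(loci, on="pair_id", how="inner")
    out = out.rename(columns={"start": "pos"})
    return out[["individual", "contig", "pos", "count_a", "count_b"]]


def count_alleles(reads_by_sample, placed: pd.DataFrame, markers: pd.DataFrame, k: int) -> pd.DataFrame:
    """Count exact diagnostic-allele observations per sample per locus.

    Every length-k window of every read is checked against the marker lookup
    (a read may hit several loci and is counted at each); hits are reported
    at the placed coordinates.  Returns a long DataFrame with one row per
    (sample, locus) having coverage: ``individual, contig, pos, count_a,
    count_b``.
    """
    placed_pairs = set(placed["pair_id"].unique())
    m = markers[markers["pair_id"].isin(placed_pairs)]
    return pair_counts_to_alleles(count_pair_hits(reads_by_sample, m, k), placed)


def call_genotypes(counts: pd.DataFrame, min_allele: int = 2) -> pd.DataFrame:
    """Threshold allele counts into raw genotype calls.

    AA if ``count_a >= min_allele`` and ``count_b == 0`` (BB symmetric);
    AB if both alleles observed at least once; otherwise NA.  The singleton
    homozygote guard (``min_allele``) suppresses isolated sequencing errors.
    """
    ca = counts["count_a"].to_numpy()
    cb = counts["count_b"].to_numpy()
    call = np.full(len(counts), "NA", dtype=object)
    call[(ca >= min_allele) & (cb == 0)] = "AA"
    call[(cb >= min_allele) & (ca == 0)] = "BB"
    call[(ca >= 1) & (cb >= 1)] = "AB"
    out = counts.copy()
    out["call"] = call
    return out


# ---------------------------------------------------------------------------
# consensus binning
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Consensus genotypes over windows tiling each contig.

    ``loci`` has columns ``contig, window_index, start, end``; ``codes`` is a
    (n_loci, n_individuals) uint8 array over {0:A, 1:H, 2:B, 3:U}.  U is
    treated as missing everywhere downstream.
    """

    loci: pd.DataFrame
    individuals: list[str]
    codes: np.ndarray

    def __post_init__(self):
        if self.codes.shape != (len(self.loci), len(self.individuals)):
            raise ValueError("codes shape does not match loci x individuals")
        if self.loci.duplicated(["contig", "window_index"]).any():
            raise ValueError("duplicate locus labels")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")

    @property
    def locus_labels(self) -> list[str]:
        return [f"{c}:{w}" for c, w in zip(self.loci["contig"], self.loci["window_index"])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            CODE_LETTERS[self.codes], index=self.locus_labels, columns=self.individuals
        )

    def write_tsv(self, path: str) -> None:
        self.to_frame().rename_axis("locus").to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, loci: pd.DataFrame) -> "GenotypeMatrix":
        letters = frame.to_numpy(dtype="U1")
        codes = np.full(letters.shape, U, dtype=np.uint8)
        for i, ch in enumerate(CODE_LETTERS):
            codes[letters == ch] = i
        return cls(loci=loci, individuals=list(frame.columns), codes=codes)


def contig_windows(contig_lengths: dict[str, int], window: int) -> pd.DataFrame:
    """Half-open windows anchored at 0 tiling each contig; the terminal
    window may be shorter."""
    rows = []
    for contig, length in contig_lengths.items():
        n_w = max(1, -(-length // window))
        for w in range(n_w):
            rows.append((contig, w, w * window, min((w + 1) * window, length)))
    return pd.DataFrame(rows, columns=["contig", "window_index", "start", "end"])


def bin_consensus(
    calls: pd.DataFrame,
    contig_lengths: dict[str, int],
    window: int = 14_000,
    min_calls: int = 2,
    individuals: list[str] | None = None,
) -> GenotypeMatrix:
    """Majority-rule binning of raw calls into consensus windows.

    Per individual per window, the consensus is the strictly most frequent
    genotype among non-NA raw calls if it occurs at least ``min_calls`` times
    and beats every rival; ties or too few informative calls give U.
    """
    loci = contig_windows(contig_lengths, window)
    if individuals is None:
        individuals = sorted(calls["individual"].unique())
    ind_of = {s: i for i, s in enumerate(individuals)}
    n_loci, n_ind = len(loci), len(individuals)
    votes = np.zeros((n_loci, n_ind, 3), dtype=np.int32)

    informative = calls[calls["call"].isin(["AA", "AB", "BB"])]
    if len(informative):
        contig_base = {}
        off = 0
        for contig, length in contig_lengths.items():
            contig_base[contig] = off
            off += max(1, -(-length // window))
        unknown = set(informative["contig"]) - set(contig_base)
        if unknown:
            raise KeyError(f"calls reference contigs without lengths: {sorted(unknown)}")
        li = (
            informative["contig"].map(contig_base).to_numpy(dtype=np.int64)
            + informative["pos"].to_numpy(dtype=np.int64) // window
        )
        mapped = informative["individual"].map(ind_of)
        if mapped.isna().any():
            bad = set(informative["individual"]) - set(ind_of)
            raise KeyError(f"calls reference unknown individuals: {sorted(bad)[:5]}")
        ii = mapped.to_numpy(dtype=np.int64)
        gi = informative["call"].map({"AA": 0, "AB": 1, "BB": 2}).to_numpy(dtype=np.int64)
        np.add.at(votes, (li, ii, gi), 1)

    order = np.argsort(votes, axis=2)
    best = order[:, :, 2]
    best_n = np.take_along_axis(votes, order[:, :, 2:3], axis=2)[:, :, 0]
    second_n = np.take_along_axis(votes, order[:, :, 1:2], axis=2)[:, :, 0]
    codes = np.where((best_n >= min_calls) & (best_n > second_n), best, U).astype(np.uint8)
    return GenotypeMatrix(loci=loci, individuals=list(individuals), codes=codes)
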