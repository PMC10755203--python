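"""Exact 2-bit-packed k-mer machinery.

Every length-k window over {A,C,G,T} is represented exactly by a pair of
``uint64`` values ``(hi, lo)``: ``hi`` packs the first ``ceil(k/2)`` bases and
``lo`` the remainder, two bits per base, most-significant base first.  Because
the base encoding A<C<G<T matches alphabetical order, comparing ``(hi, lo)``
lexicographically compares the underlying k-mer strings, so the canonical form
(the lexicographic minimum of a k-mer and its reverse complement) can be chosen
by vectorised integer comparison.  The packing is exact for k <= 64 — there are
no hash collisions anywhere in this module; the 64-bit mixed key used for
sorted lookup is always verified against the full ``(hi, lo)`` pair.

Only odd k is supported throughout the package (an odd-length k-mer can never
equal its own reverse complement, so "canonical" is unambiguous).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "encode",
    "revcomp",
    "revcomp_codes",
    "pack_windows",
    "pack_windows_both",
    "pack_kmer",
    "canonical_kmer",
    "decode_many",
    "decode_one",
    "KmerCounts",
    "PackedIndex",
]

# ASCII byte -> 2-bit code; 4 marks anything that is not an unambiguous base.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_COMP = np.full(256, ord("N"), dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCATGCA"):
    _COMP[_a] = _b
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Map a nucleotide string to a uint8 array of 2-bit codes (4 = invalid)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    arr = _COMP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return arr[::-1].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a 2-bit code array; invalid codes stay invalid."""
    return np.where(codes > 3, np.uint8(4), (3 - codes).astype(np.uint8))[::-1]


def _check_k(k: int) -> None:
    if not (3 <= k <= 64):
        raise ValueError(f"k must be in [3, 64], got {k}")
    if k % 2 == 0:
        raise ValueError(f"k must be odd (canonical form is ambiguous for even k), got {k}")


def _split(k: int) -> tuple[int, int]:
    h = (k + 1) // 2
    return h, k - h


def pack_windows(codes: np.ndarray, k: int, chunk: int = 1 << 21):
    """Pack every length-k window of ``codes`` into (hi, lo) uint64 arrays.

    Returns ``(hi, lo, valid)`` with one entry per window start; ``valid`` is
    False for windows containing any non-ACGT position.  Packed values of
    invalid windows are arbitrary and must be masked by the caller.
    """
    _check_k(k)
    n = codes.size - k + 1
    if n <= 0:
        z = np.empty(0, dtype=np.uint64)
        return z, z.copy(), np.empty(0, dtype=bool)
    h, l = _split(k)
    bad = (codes > 3).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    safe = np.where(codes > 3, np.uint8(0), codes).astype(np.uint64)
    # shifted-slice accumulation: sequential memory access beats a strided
    # window-matrix product by an order of magnitude here
    hi = np.zeros(n, dtype=np.uint64)
    lo = np.zeros(n, dtype=np.uint64)
    for j in range(h):
        hi += safe[j : j + n] << np.uint64(2 * (h - 1 - j))
    for j in range(l):
        lo += safe[h + j : h + j + n] << np.uint64(2 * (l - 1 - j))
    return hi, lo, valid


def pack_windows_both(codes: np.ndarray, k: int):
    """Forward and reverse-complement packings of every window.

    Returns ``(fhi, flo, rhi, rlo, valid)`` where ``(rhi[i], rlo[i])`` packs the
    reverse complement of window i.
    """
    fhi, flo, valid = pack_windows(codes, k)
    rc = revcomp_codes(codes)
    rhi_all, rlo_all, _ = pack_windows(rc, k)
    # forward window i corresponds to window n-1-i of the reverse complement
    return fhi, flo, rhi_all[::-1].copy(), rlo_all[::-1].copy(), valid


def pack_kmer(kmer: str, k: int | None = None) -> tuple[int, int]:
    """Pack a single k-mer string into its (hi, lo) pair."""
    k = len(kmer) if k is None else k
    if len(kmer) != k:
        raise ValueError("k-mer length mismatch")
    codes = encode(kmer)
    if (codes > 3).any():
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    hi, lo, _ = pack_windows(codes, k)
    return int(hi[0]), int(lo[0])


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def unpack_codes(hi: np.ndarray, lo: np.ndarray, k: int) -> np.ndarray:
    """Unpack (hi, lo) arrays to an (n, k) matrix of 2-bit codes."""
    _check_k(k)
    h, l = _split(k)
    n = hi.size
    out = np.empty((n, k), dtype=np.uint8)
    for j in range(h):
        out[:, h - 1 - j] = (hi >> np.uint64(2 * j)).astype(np.uint64) & np.uint64(3)
    for j in range(l):
        out[:, k - 1 - j] = (lo >> np.uint64(2 * j)).astype(np.uint64) & np.uint64(3)
    return out


def pack_code_matrix(codes: np.ndarray):
    """Pack an (n, k) matrix of 2-bit codes into (hi, lo) uint64 arrays."""
    n, k = codes.shape
    _check_k(k)
    h, l = _split(k)
    ph = (4 ** np.arange(h - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    pl = (4 ** np.arange(l - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    m = codes.astype(np.uint64)
    return m[:, :h] @ ph, m[:, h:] @ pl


def revcomp_packed(hi: np.ndarray, lo: np.ndarray, k: int):
    """Reverse-complement packed k-mers."""
    codes = unpack_codes(hi, lo, k)
    return pack_code_matrix(3 - codes[:, ::-1])


def decode_many(hi: np.ndarray, lo: np.ndarray, k: int) -> np.ndarray:
    """Decode (hi, lo) arrays back to an array of k-mer byte strings."""
    n = hi.size
    out = unpack_codes(hi, lo, k)
    return _BASES[out].reshape(n, k).view(f"S{k}").ravel()


def decode_one(hi: int, lo: int, k: int) -> str:
    return decode_many(np.array([hi], dtype=np.uint64), np.array([lo], dtype=np.uint64), k)[0].decode()


_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_C1 = np.uint64(0x9E3779B97F4A7C15)


def mix64(hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Well-mixed 64-bit key for a (hi, lo) pair (splitmix64 finaliser).

    Used only as a sort key; equality is always re-verified on (hi, lo).
    """
    z = (hi * _C1) ^ (lo + _C1)
    z = (z ^ (z >> np.uint64(30))) * _M1
    z = (z ^ (z >> np.uint64(27))) * _M2
    return z ^ (z >> np.uint64(31))


class PackedIndex:
    """Sorted exact-lookup index over packed (hi, lo) k-mer keys.

    Lookup is by a mixed 64-bit sort key with full verification against the
    exact 102-bit packing, including a linear probe across mixed-key
    collisions, so ``find`` is exact.
    """

    _FILTER_BITS = 22  # 4M-slot membership prefilter

    def __init__(self, hi: np.ndarray, lo: np.ndarray):
        hi = np.asarray(hi, dtype=np.uint64)
        lo = np.asarray(lo, dtype=np.uint64)
        key = mix64(hi, lo)
        order = np.argsort(key, kind="stable")
        self.key = key[order]
        self.hi = hi[order]
        self.lo = lo[order]
        self.order = order  # position in the original arrays
        # one-sided membership prefilter: a query whose slot is clear cannot
        # be present; dramatically cuts binary searches on sparse-hit scans
        self._mask = np.uint64((1 << self._FILTER_BITS) - 1)
        self._filter = np.zeros(1 << self._FILTER_BITS, dtype=bool)
        self._filter[(self.key & self._mask).astype(np.int64)] = True

    def __len__(self) -> int:
        return self.key.size

    def find(self, q_hi: np.ndarray, q_lo: np.ndarray) -> np.ndarray:
        """Return, per query, the original-array position of a match, or -1."""
        q_hi = np.asarray(q_hi, dtype=np.uint64)
        q_lo = np.asarray(q_lo, dtype=np.uint64)
        qk_all = mix64(q_hi, q_lo)
        res = np.full(q_hi.size, -1, dtype=np.int64)
        maybe = np.flatnonzero(self._filter[(qk_all & self._mask).astype(np.int64)])
        if maybe.size == 0:
            return res
        qk = qk_all[maybe]
        q_hi, q_lo = q_hi[maybe], q_lo[maybe]
        pos = np.searchsorted(self.key, qk, side="left")
        sub = np.full(maybe.size, -1, dtype=np.int64)
        active = np.arange(maybe.size)
        cand = pos
        n = self.key.size
        while active.size:
            inb = cand < n
            active, cand = active[inb], cand[inb]
            if not active.size:
                break
            same_key = self.key[cand] == qk[active]
            active, cand = active[same_key], cand[same_key]
            if not active.size:
                break
            hit = (self.hi[cand] == q_hi[active]) & (self.lo[cand] == q_lo[active])
            sub[active[hit]] = self.order[cand[hit]]
            # mixed-key collision (different 102-bit value, same 64-bit key):
            # probe the next slot.  Essentially never taken.
            active, cand = active[~hit], cand[~hit] + 1
        res[maybe] = sub
        return res


def _sorted_unique_counts(hi: np.ndarray, lo: np.ndarray):
    """Unique (hi, lo) pairs in lexicographic order with multiplicities."""
    if hi.size == 0:
        z = np.empty(0, dtype=np.uint64)
        return z, z.copy(), np.empty(0, dtype=np.int64)
    order = np.lexsort((lo, hi))
    hi_s, lo_s = hi[order], lo[order]
    new = np.empty(hi_s.size, dtype=bool)
    new[0] = True
    new[1:] = (hi_s[1:] != hi_s[:-1]) | (lo_s[1:] != lo_s[:-1])
    starts = np.flatnonzero(new)
    counts = np.diff(np.append(starts, hi_s.size))
    return hi_s[starts], lo_s[starts], counts


class KmerCounts:
    """Canonical k-mer count table backed by packed uint64 arrays.

    Behaves like a read-only mapping from k-mer strings to counts; looking up a
    k-mer canonicalises it first.  Built from arbitrary iterables of sequences
    (reads or genome records); windows containing N are skipped.
    """

    def __init__(self, k: int, hi: np.ndarray, lo: np.ndarray, counts: np.ndarray):
        _check_k(k)
        self.k = k
        self.hi = np.asarray(hi, dtype=np.uint64)
        self.lo = np.asarray(lo, dtype=np.uint64)
        self.counts = np.asarray(counts, dtype=np.int64)
        self._index = PackedIndex(self.hi, self.lo)

    @classmethod
    def from_sequences(cls, sequences, k: int, chunk_bases: int = 8 << 20) -> "KmerCounts":
        """Count canonical k-mers over an iterable of sequence strings."""
        _check_k(k)
        parts_hi: list[np.ndarray] = []
        parts_lo: list[np.ndarray] = []
        parts_ct: list[np.ndarray] = []
        buf: list[str] = []
        size = 0

        def flush():
            nonlocal buf, size
            if not buf:
                return
            joined = ("N".join(buf))
            codes = encode(joined)
            fhi, flo, rhi, rlo, valid = pack_windows_both(codes, k)
            use_f = (fhi < rhi) | ((fhi == rhi) & (flo <= rlo))
            chi = np.where(use_f, fhi, rhi)[valid]
            clo = np.where(use_f, flo, rlo)[valid]
            uh, ul, ct = _sorted_unique_counts(chi, clo)
            parts_hi.append(uh)
            parts_lo.append(ul)
            parts_ct.append(ct)
            buf, size = [], 0

        for seq in sequences:
            if not seq:
                continue
            buf.append(seq)
            size += len(seq) + 1
            if size >= chunk_bases:
                flush()
        flush()
        if not parts_hi:
            z = np.empty(0, dtype=np.uint64)
            return cls(k, z, z.copy(), np.empty(0, dtype=np.int64))
        hi = np.concatenate(parts_hi)
        lo = np.concatenate(parts_lo)
        ct = np.concatenate(parts_ct)
        # merge per-chunk tables
        order = np.lexsort((lo, hi))
        hi, lo, ct = hi[order], lo[order], ct[order]
        new = np.empty(hi.size, dtype=bool)
        if hi.size:
            new[0] = True
            new[1:] = (hi[1:] != hi[:-1]) | (lo[1:] != lo[:-1])
        starts = np.flatnonzero(new)
        grp = np.cumsum(new) - 1
        merged = np.bincount(grp, weights=ct).astype(np.int64)
        return cls(k, hi[starts], lo[starts], merged)

    def __len__(self) -> int:
        return self.hi.size

    def lookup(self, q_hi: np.ndarray, q_lo: np.ndarray) -> np.ndarray:
        """Vectorised counts for packed canonical queries (0 where absent)."""
        pos = self._index.find(q_hi, q_lo)
        out = np.zeros(pos.size, dtype=np.int64)
        hitmask = pos >= 0
        out[hitmask] = self.counts[pos[hitmask]]
        return out

    def get(self, kmer: str, default: int = 0) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        hi, lo = pack_kmer(canonical_kmer(kmer.upper()))
        c = self.lookup(np.array([hi], dtype=np.uint64), np.array([lo], dtype=np.uint64))[0]
        return int(c) if c else default

    def __getitem__(self, kmer: str) -> int:
        return self.get(kmer)

    def __contains__(self, kmer: str) -> bool:
        return self.get(kmer) > 0

    def kmer_strings(self) -> np.ndarray:
        return decode_many(self.hi, self.lo, self.k)

    def to_dict(self) -> dict[str, int]:
        return {
            s.decode(): int(c) for s, c in zip(self.kmer_strings(), self.counts)
        }
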