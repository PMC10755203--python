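"""Synthetic F2 GBS study generator with full ground truth.

Emulates the data behind a genetic-map-guided genome finishing experiment:

* two fully inbred parental haplotypes that differ only by SNVs,
* an F2 intercross population of recombinant mosaics (no crossover
  interference: Poisson crossover counts, uniform breakpoints),
* ApeKI (GCWGC, cut G^CWGC) reduced-representation libraries sequenced as
  barcoded single-end reads with substitution errors,
* a draft assembly made by fragmenting the parent-A genome, optionally with
  engineered cross-chromosome chimeric joins,

plus a :class:`TruthSet` recording every latent variable so downstream
genotyping, mapping and scaffolding can be scored against known truth.

Only fragment ends carrying the ApeKI ``CWGC`` remnant are sequenced (a
chromosome-terminal blunt end has nothing to ligate to).  The bottom-strand
read of a fragment ``[s, e)`` starts at the 3-base 5' overhang of the
downstream cut, i.e. it is ``revcomp(seq[s:e+3])`` truncated to the read
length, which makes both reads of a fragment begin with the remnant.
Sequencing errors are applied to the genomic portion of a read only; barcodes
are error-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmers import encode, revcomp

__all__ = [
    "ChimeraSpec",
    "SimConfig",
    "TruthSet",
    "simulate_parents",
    "simulate_f2_population",
    "digest_genome",
    "simulate_gbs_run",
    "fragment_reference",
    "generate_barcodes",
    "parse_read_id",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.full(256, 0, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP[_a] = _b

REMNANT = "CWGC"
REMNANT_LEN = 4
OVERHANG = 3  # length of the 5' CWG overhang left by ApeKI


@dataclass(frozen=True)
class ChimeraSpec:
    """An engineered misjoin: two segments from *different* chromosomes glued
    into one contig.  Coordinates are 0-based half-open on parent A."""

    segment_1: tuple[str, int, int]
    segment_2: tuple[str, int, int]

    def __post_init__(self):
        if self.segment_1[0] == self.segment_2[0]:
            raise ValueError(
                "chimera segments must come from different chromosomes, "
                f"both are on {self.segment_1[0]}"
            )
        for chrom, s, e in (self.segment_1, self.segment_2):
            if not (0 <= s < e):
                raise ValueError(f"invalid chimera segment ({chrom}, {s}, {e})")


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cross.

    Defaults encode the target study design: 9 chromosomes, 288 F2 individuals,
    single-end 100-bp reads, and desk-scale 500-kb chromosomes with an SNV
    rate of 0.002/bp between the inbred parents.
    """

    n_chromosomes: int = 9
    chromosome_length: int = 500_000
    snv_rate: float = 0.002
    n_individuals: int = 288
    crossover_mean: float = 1.5
    read_length: int = 100
    error_rate: float = 0.0
    mean_depth: float = 4.0
    size_selection: tuple[int, int] = (60, 400)
    barcodes: list[tuple[str, str]] | None = None
    n_contigs: int = 60
    chimeras: int | list[ChimeraSpec] = 0
    chimera_seg_range: tuple[int, int] = (30_000, 80_000)
    min_contig_length: int = 2_000
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.snv_rate < 1:
            raise ValueError(f"snv_rate must be in [0, 1), got {self.snv_rate}")
        if not 0 <= self.error_rate < 1:
            raise ValueError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if self.n_chromosomes < 1 or self.chromosome_length < 100:
            raise ValueError("need at least 1 chromosome of >= 100 bp")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if self.size_selection[0] > self.size_selection[1]:
            raise ValueError(f"empty size-selection window {self.size_selection}")
        if self.barcodes is None:
            self.barcodes = generate_barcodes(self.n_individuals, seed=self.seed)
        if len(self.barcodes) != self.n_individuals:
            raise ValueError(
                f"{len(self.barcodes)} barcodes for {self.n_individuals} individuals"
            )
        seqs = [b for _, b in self.barcodes]
        if len(set(seqs)) != len(seqs):
            raise ValueError("barcode sequences are not unique")
        longest = max(len(b) for b in seqs)
        if self.read_length <= longest + REMNANT_LEN:
            raise ValueError(
                f"read_length {self.read_length} must exceed the longest barcode "
                f"({longest}) plus the {REMNANT_LEN}-bp restriction remnant"
            )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.barcodes]


def generate_barcodes(n: int, seed: int = 0, lengths: tuple[int, int] = (4, 8)) -> list[tuple[str, str]]:
    """Generate ``n`` unique, prefix-free GBS barcodes with mixed lengths.

    Prefix-freeness makes exact longest-first demultiplexing unambiguous.
    """
    rng = np.random.default_rng([seed, 0xBA5C0DE])
    out: list[str] = []
    seen: set[str] = set()
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 100_000:
            raise RuntimeError("barcode generation failed to converge")
        ln = int(rng.integers(lengths[0], lengths[1] + 1))
        bc = "".join("ACGT"[i] for i in rng.integers(0, 4, ln))
        if bc in seen:
            continue
        if any(bc.startswith(o) or o.startswith(bc) for o in out):
            continue
        seen.add(bc)
        out.append(bc)
    width = len(str(n))
    return [(f"F2_{i + 1:0{width}d}", bc) for i, bc in enumerate(out)]


@dataclass
class TruthSet:
    """Ground truth of a simulated study.

    ``gametes`` holds one row per mosaic segment: columns ``individual``,
    ``chromosome``, ``gamete`` (0/1), ``start``, ``end`` (0-based half-open)
    and ``founder`` (0 = parent A, 1 = parent B).
    """

    haplotype_a: dict[str, str] = field(default_factory=dict)
    haplotype_b: dict[str, str] = field(default_factory=dict)
    snv_table: pd.DataFrame | None = None
    gametes: pd.DataFrame | None = None
    individuals: list[str] = field(default_factory=list)
    contig_layout: pd.DataFrame | None = None
    chimera_truth: pd.DataFrame | None = None

    # -- lazy caches -------------------------------------------------------
    def __post_init__(self):
        self._snv_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._gamete_cache: dict[tuple[str, str, int], tuple[np.ndarray, np.ndarray]] | None = None

    def chrom_length(self, chrom: str) -> int:
        return len(self.haplotype_a[chrom])

    def snv_arrays(self, chrom: str):
        """(positions, allele_a ascii, allele_b ascii) for one chromosome."""
        if chrom not in self._snv_cache:
            sub = self.snv_table[self.snv_table["chromosome"] == chrom]
            pos = sub["position"].to_numpy(dtype=np.int64)
            a = np.frombuffer("".join(sub["allele_a"]).encode(), dtype=np.uint8)
            b = np.frombuffer("".join(sub["allele_b"]).encode(), dtype=np.uint8)
            self._snv_cache[chrom] = (pos, a, b)
        return self._snv_cache[chrom]

    def _gamete_index(self):
        if self._gamete_cache is None:
            cache: dict[tuple[str, str, int], tuple[np.ndarray, np.ndarray]] = {}
            for (ind, chrom, g), sub in self.gametes.groupby(
                ["individual", "chromosome", "gamete"], sort=False
            ):
                sub = sub.sort_values("start")
                cache[(ind, chrom, int(g))] = (
                    sub["start"].to_numpy(dtype=np.int64),
                    sub["founder"].to_numpy(dtype=np.int8),
                )
            self._gamete_cache = cache
        return self._gamete_cache

    def founder_at(self, individual: str, chrom: str, gamete: int, positions: np.ndarray) -> np.ndarray:
        """Founder label (0=A, 1=B) of one gamete at the given positions."""
        starts, founders = self._gamete_index()[(individual, chrom, gamete)]
        idx = np.searchsorted(starts, positions, side="right") - 1
        return founders[idx]

    def genotype_dosage(self, chrom: str, positions: np.ndarray) -> pd.DataFrame:
        """Dose of the parent-B allele (0/1/2) at positions x individuals."""
        out = np.empty((len(positions), len(self.individuals)), dtype=np.int8)
        positions = np.asarray(positions, dtype=np.int64)
        for j, ind in enumerate(self.individuals):
            out[:, j] = self.founder_at(ind, chrom, 0, positions).astype(np.int8) + self.founder_at(
                ind, chrom, 1, positions
            )
        return pd.DataFrame(out, columns=self.individuals)

    def mosaic_ascii(self, individual: str, chrom: str, gamete: int) -> np.ndarray:
        """ASCII byte array of one recombinant haplotype copy."""
        arr = np.frombuffer(self.haplotype_a[chrom].encode(), dtype=np.uint8).copy()
        pos, _a, b = self.snv_arrays(chrom)
        if pos.size:
            founder = self.founder_at(individual, chrom, gamete, pos)
            sel = founder == 1
            arr[pos[sel]] = b[sel]
        return arr


# ---------------------------------------------------------------------------
# parents
# ---------------------------------------------------------------------------

def simulate_parents(config: SimConfig) -> TruthSet:
    """Draw parent A uniformly over {A,C,G,T} and mutate each position into a
    distinct base in parent B independently with probability ``snv_rate``."""
    rng = np.random.default_rng([config.seed, 1])
    hap_a: dict[str, str] = {}
    hap_b: dict[str, str] = {}
    rows = []
    for chrom in config.chrom_names:
        L = config.chromosome_length
        codes = rng.integers(0, 4, L, dtype=np.uint8)
        ascii_a = _BASES[codes]
        pos = np.flatnonzero(rng.random(L) < config.snv_rate)
        alt = (codes[pos] + rng.integers(1, 4, pos.size, dtype=np.uint8)) % 4
        ascii_b = ascii_a.copy()
        ascii_b[pos] = _BASES[alt]
        hap_a[chrom] = ascii_a.tobytes().decode()
        hap_b[chrom] = ascii_b.tobytes().decode()
        rows.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "position": pos,
                    "allele_a": [chr(c) for c in ascii_a[pos]],
                    "allele_b": [chr(c) for c in ascii_b[pos]],
                }
            )
        )
    snv = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["chromosome", "position", "allele_a", "allele_b"])
    )
    return TruthSet(haplotype_a=hap_a, haplotype_b=hap_b, snv_table=snv)


# ---------------------------------------------------------------------------
# F2 population
# ---------------------------------------------------------------------------

def simulate_f2_population(truth: TruthSet, config: SimConfig) -> TruthSet:
    """Add F2 gamete mosaics: Poisson(crossover_mean) crossovers per gamete per
    chromosome, uniform breakpoints, founder labels alternating from a fair
    coin — no interference."""
    rng = np.random.default_rng([config.seed, 2])
    individuals = config.sample_ids
    rows_ind, rows_chrom, rows_g, rows_s, rows_e, rows_f = [], [], [], [], [], []
    for ind in individuals:
        for chrom in config.chrom_names:
            L = truth.chrom_length(chrom)
            for g in (0, 1):
                n_cx = int(rng.poisson(config.crossover_mean))
                bps = np.sort(rng.integers(1, L, n_cx)) if n_cx else np.empty(0, dtype=np.int64)
                founder = int(rng.integers(0, 2))
                bounds = np.concatenate(([0], bps, [L]))
                for i in range(len(bounds) - 1):
                    s, e = int(bounds[i]), int(bounds[i + 1])
                    if s < e:  # coincident breakpoints cancel pairwise
                        rows_ind.append(ind)
                        rows_chrom.append(chrom)
                        rows_g.append(g)
                        rows_s.append(s)
                        rows_e.append(e)
                        rows_f.append((founder + i) % 2)
    truth.gametes = pd.DataFrame(
        {
            "individual": rows_ind,
            "chromosome": rows_chrom,
            "gamete": rows_g,
            "start": rows_s,
            "end": rows_e,
            "founder": rows_f,
        }
    )
    truth.individuals = list(individuals)
    truth._gamete_cache = None
    return truth


# ---------------------------------------------------------------------------
# ApeKI digestion
# ---------------------------------------------------------------------------

def _cut_positions(ascii_arr: np.ndarray) -> np.ndarray:
    """ApeKI cut positions (G^CWGC) on the forward strand.

    The site set {GCAGC, GCTGC} is its own reverse complement, so scanning one
    strand finds every site; overlapping matches each yield a cut.
    """
    a = ascii_arr
    if a.size < 5:
        return np.empty(0, dtype=np.int64)
    m = (
        (a[:-4] == ord("G"))
        & (a[1:-3] == ord("C"))
        & ((a[2:-2] == ord("A")) | (a[2:-2] == ord("T")))
        & (a[3:-1] == ord("G"))
        & (a[4:] == ord("C"))
    )
    return np.flatnonzero(m).astype(np.int64) + 1


def digest_genome(sequence: str) -> list[tuple[int, int]]:
    """In-silico ApeKI digest: 0-based half-open fragment coordinates.

    Fragments tile the input exactly; re-joining them in order reproduces it.
    """
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    cuts = _cut_positions(arr)
    bounds = np.concatenate(([0], cuts, [len(sequence)]))
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(bounds) - 1)]


# ---------------------------------------------------------------------------
# GBS sequencing
# ---------------------------------------------------------------------------

def parse_read_id(read_id: str) -> dict:
    """Decode the per-read truth carried in a simulated read name."""
    sample, chrom, gamete, span, strand, serial = read_id.split("|")
    s, e = span.split("-")
    return {
        "individual": sample,
        "chromosome": chrom,
        "gamete": int(gamete[1:]),
        "fragment_start": int(s),
        "fragment_end": int(e),
        "strand": strand,
        "serial": int(serial),
    }


def _apply_errors(genomic: str, rng, error_rate: float) -> str:
    arr = np.frombuffer(genomic.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < error_rate)
    if hit.size:
        codes = encode(arr[hit].tobytes())
        arr[hit] = _BASES[(codes + rng.integers(1, 4, hit.size, dtype=np.uint8)) % 4]
    return arr.tobytes().decode()


def simulate_gbs_run(truth: TruthSet, config: SimConfig, fastq_path) -> dict:
    """Digest every individual's two haplotype mosaics, size-select, and emit
    Poisson(mean_depth) barcoded single-end reads per remnant-bearing fragment
    end into one multiplexed FASTQ (Phred+33, constant quality 'I').

    Reads shorter than the read length (small fragments) are truncated, never
    padded.  Per-read truth (individual, fragment, haplotype copy, strand) is
    encoded in the read name; see :func:`parse_read_id`.
    """
    rng = np.random.default_rng([config.seed, 3])
    lo_sz, hi_sz = config.size_selection
    per_sample = {}
    total = 0
    buf: list[str] = []
    with open(fastq_path, "w") as fh:
        for ind, barcode in config.barcodes:
            cap = config.read_length - len(barcode)
            n_sample = 0
            for chrom in config.chrom_names:
                L = truth.chrom_length(chrom)
                for g in (0, 1):
                    arr = truth.mosaic_ascii(ind, chrom, g)
                    cuts = _cut_positions(arr)
                    bounds = np.concatenate(([0], cuts, [L]))
                    starts, ends = bounds[:-1], bounds[1:]
                    lens = ends - starts
                    keep = (lens >= lo_sz) & (lens <= hi_sz)
                    ks, ke = starts[keep], ends[keep]
                    # an end is sequenced only if it carries the CWGC remnant
                    top_ok = ks > 0
                    bot_ok = ke < L
                    n_ends = int(top_ok.sum() + bot_ok.sum())
                    depths = rng.poisson(config.mean_depth, n_ends)
                    di = 0
                    for s, e, t_ok, b_ok in zip(ks, ke, top_ok, bot_ok):
                        s, e = int(s), int(e)
                        for strand in ("T", "B"):
                            if strand == "T":
                                if not t_ok:
                                    continue
                                genomic = arr[s : s + cap].tobytes().decode()
                            else:
                                if not b_ok:
                                    continue
                                seg = _COMP[arr[s : e + OVERHANG]][::-1]
                                genomic = seg[:cap].tobytes().decode()
                            d = int(depths[di])
                            di += 1
                            for j in range(d):
                                gseq = (
                                    genomic
                                    if config.error_rate == 0
                                    else _apply_errors(genomic, rng, config.error_rate)
                                )
                                seq = barcode + gseq
                                rid = f"{ind}|{chrom}|g{g}|{s}-{e}|{strand}|{j}"
                                buf.append(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}")
                                n_sample += 1
                            if len(buf) >= 50_000:
                                fh.write("\n".join(buf) + "\n")
                                buf.clear()
            per_sample[ind] = n_sample
            total += n_sample
        if buf:
            fh.write("\n".join(buf) + "\n")
    return {"n_reads": total, "per_sample": per_sample}


# ---------------------------------------------------------------------------
# draft assembly
# ---------------------------------------------------------------------------

def _random_chimera_specs(truth: TruthSet, config: SimConfig, n: int, rng) -> list[ChimeraSpec]:
    chroms = list(truth.haplotype_a)
    if len(chroms) < 2:
        raise ValueError("chimeras need at least two chromosomes")
    lo, hi = config.chimera_seg_range
    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def grab() -> tuple[str, int, int]:
        for _ in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = truth.chrom_length(chrom)
            hi_eff = max(2, min(hi, L // 3))
            lo_eff = min(lo, hi_eff)
            ln = int(rng.integers(lo_eff, hi_eff + 1))
            s = int(rng.integers(0, L - ln))
            if all(e0 <= s or s + ln <= s0 for s0, e0 in reserved[chrom]):
                reserved[chrom].append((s, s + ln))
                return chrom, s, s + ln
        raise RuntimeError("could not place chimera segments; genome too small")

    specs = []
    while len(specs) < n:
        a = grab()
        b = grab()
        if a[0] == b[0]:
            # same chromosome drawn twice: release b and retry
            reserved[b[0]].remove((b[1], b[2]))
            reserved[a[0]].remove((a[1], a[2]))
            continue
        specs.append(ChimeraSpec(a, b))
    return specs


def fragment_reference(
    truth: TruthSet, config: SimConfig, chimeras: list[ChimeraSpec] | None = None
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Fragment the parent-A genome into a draft assembly of ``n_contigs``.

    Chimera segments are reserved first (rejecting overlaps), the remaining
    genome is cut at random positions with a minimum length enforced, and each
    chimeric contig is the concatenation of its two cross-chromosome segments,
    so the contigs jointly cover every chromosome exactly once.

    Returns ``(contigs, contig_layout, chimera_truth)``; the layout has one
    row per source segment (two for a chimeric contig) with columns ``contig``,
    ``chromosome``, ``start``, ``end``, ``strand``, ``part_index``.
    """
    rng = np.random.default_rng([config.seed, 4])
    if chimeras is None:
        chimeras = (
            _random_chimera_specs(truth, config, config.chimeras, rng)
            if isinstance(config.chimeras, int) and config.chimeras > 0
            else (config.chimeras if isinstance(config.chimeras, list) else [])
        )
    chroms = list(truth.haplotype_a)
    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for spec in chimeras:
        for chrom, s, e in (spec.segment_1, spec.segment_2):
            if chrom not in reserved:
                raise ValueError(f"unknown chromosome in chimera spec: {chrom}")
            if e > truth.chrom_length(chrom):
                raise ValueError(f"chimera segment ({chrom}, {s}, {e}) exceeds chromosome")
            for s0, e0 in reserved[chrom]:
                if s < e0 and s0 < e:
                    raise ValueError(
                        f"chimera segment ({chrom}, {s}, {e}) overlaps an "
                        f"already-consumed region ({chrom}, {s0}, {e0})"
                    )
            reserved[chrom].append((s, e))

    n_plain = config.n_contigs - len(chimeras)
    if n_plain < len(chroms):
        raise ValueError("n_contigs too small for the chromosome count and chimeras")

    # complement of the reserved regions, per chromosome
    free: list[tuple[str, int, int]] = []
    for chrom in chroms:
        L = truth.chrom_length(chrom)
        prev = 0
        for s, e in sorted(reserved[chrom]):
            if prev < s:
                free.append((chrom, prev, s))
            prev = e
        if prev < L:
            free.append((chrom, prev, L))

    min_len = config.min_contig_length
    total_free = sum(e - s for _, s, e in free)
    # allocate plain contigs to free intervals, largest-remainder style
    quotas = np.maximum(1, np.floor([n_plain * (e - s) / total_free for _, s, e in free]).astype(int))
    while quotas.sum() > n_plain:
        quotas[int(np.argmax(quotas))] -= 1
    while quotas.sum() < n_plain:
        lens = np.array([e - s for _, s, e in free]) / quotas
        quotas[int(np.argmax(lens))] += 1

    pieces: list[list[tuple[str, int, int]]] = []  # each entry: segment list of one contig
    for (chrom, s, e), q in zip(free, quotas):
        q = int(q)
        Lint = e - s
        q = max(1, min(q, Lint // max(min_len, 1)))
        if q == 1:
            pieces.append([(chrom, s, e)])
            continue
        slack = Lint - q * min_len
        offs = np.sort(rng.integers(0, slack + 1, q - 1))
        cuts = s + offs + min_len * np.arange(1, q)
        bounds = np.concatenate(([s], cuts, [e]))
        for i in range(q):
            pieces.append([(chrom, int(bounds[i]), int(bounds[i + 1]))])
    chim_first_idx = len(pieces)
    for spec in chimeras:
        pieces.append([spec.segment_1, spec.segment_2])

    order = rng.permutation(len(pieces))
    width = max(4, len(str(len(pieces))))
    layout_rows = []
    chim_rows = []
    contigs: dict[str, str] = {}
    for new_i, old_i in enumerate(order):
        cid = f"ctg{new_i + 1:0{width}d}"
        segs = pieces[old_i]
        seq = "".join(truth.haplotype_a[c][s:e] for c, s, e in segs)
        contigs[cid] = seq
        for pi, (c, s, e) in enumerate(segs):
            layout_rows.append((cid, c, s, e, "+", pi))
        if old_i >= chim_first_idx:
            chim_rows.append((cid, segs[0][2] - segs[0][1]))
    layout = pd.DataFrame(
        layout_rows, columns=["contig", "chromosome", "start", "end", "strand", "part_index"]
    )
    chim = pd.DataFrame(chim_rows, columns=["contig", "junction_offset"])
    truth.contig_layout = layout
    truth.chimera_truth = chim
    return contigs, layout, chim
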