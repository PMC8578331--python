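"""Exact enumeration of Cas9 target sites and Hamming-distance neighborhoods.

A :class:`TargetIndex` records every position in a genome where a k-mer
protospacer (k = 19 or 20) sits immediately 5' of a PAM (default NGG) on
either strand.  Querying the index with a guide sequence returns every site
whose protospacer is within a bounded Hamming distance (substitutions only;
the PAM is never counted) of the guide — the H0..H3 neighborhood that drives
off-target toxicity in essentiality screens.

Coordinates are 0-based and reported on the reference + strand: ``start`` is
the leftmost genomic position of the protospacer regardless of strand, and
the stored protospacer/PAM always read 5'->3' on the cutting strand, so a
minus-strand site stores the reverse complement of the genomic window.
Windows containing non-ACGT characters are skipped entirely.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._trie import decode_key, encode_kmers, query_sorted_keys

__all__ = [
    "TargetSite",
    "TargetIndex",
    "NeighborCounts",
    "build_target_index",
    "hamming_neighbors",
    "neighbor_counts",
    "brute_force_site_scan",
    "read_fasta",
    "write_bed",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DEFAULT_PAMS = ("NGG",)
DEFAULT_ALT_PATTERN = r"_alt"
_BRUTE_FORCE_SIZE_GUARD = 50_000_000


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A=0 C=1 G=2 T=3, anything else 255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def _validate_pams(pam_patterns: Iterable[str]) -> tuple[str, ...]:
    pams = tuple(str(p).upper() for p in pam_patterns)
    if not pams:
        raise ValueError("at least one PAM pattern is required")
    for p in pams:
        if len(p) != 3 or any(c not in IUPAC for c in p):
            raise ValueError(f"invalid IUPAC PAM pattern: {p!r}")
    return pams


def _expand_pams(pam_patterns: Sequence[str]) -> frozenset[str]:
    out: set[str] = set()
    for pat in pam_patterns:
        opts = [IUPAC[c] for c in pat]
        out.update(a + b + c for a in opts[0] for b in opts[1] for c in opts[2])
    return frozenset(out)


def _validate_guide(guide: str, k: int) -> str:
    guide = guide.upper()
    if len(guide) != k:
        raise ValueError(f"guide length {len(guide)} != index k={k}: {guide!r}")
    if any(c not in "ACGT" for c in guide):
        raise ValueError(f"guide contains non-ACGT characters: {guide!r}")
    return guide


@dataclass(frozen=True, order=True)
class TargetSite:
    """A protospacer+PAM occurrence in the genome.

    ``start`` is the 0-based + strand coordinate of the protospacer's
    leftmost base; ``protospacer`` and ``pam`` read 5'->3' on the cutting
    strand.  ``distance`` is the Hamming distance to the query guide and is
    only meaningful on query results.
    """

    chrom: str
    start: int
    strand: str
    protospacer: str
    pam: str
    distance: int = -1


@dataclass(frozen=True)
class NeighborCounts:
    """Tally of target sites at Hamming distance 0..3 from a guide."""

    H0: int = 0
    H1: int = 0
    H2: int = 0
    H3: int = 0

    @property
    def total(self) -> int:
        return self.H0 + self.H1 + self.H2 + self.H3

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.H0, self.H1, self.H2, self.H3)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (optionally gzipped) FASTA file into {name: sequence}."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise ValueError(f"malformed FASTA: duplicate record {rec.id!r}")
            seq = str(rec.seq)
            if not seq:
                raise ValueError(f"malformed FASTA: empty record {rec.id!r}")
            records[rec.id] = seq
    if not records:
        raise ValueError(f"malformed FASTA: no records found in {path}")
    return records


def _as_genome(genome: Mapping[str, str] | str | Path) -> dict[str, str]:
    if isinstance(genome, (str, Path)):
        return read_fasta(genome)
    return dict(genome)


def _pam_lookup(pam_patterns: Sequence[str]) -> np.ndarray:
    """(n_patterns, 3, 256) boolean membership table over base codes."""
    tables = np.zeros((len(pam_patterns), 3, 256), dtype=bool)
    for pi, pat in enumerate(pam_patterns):
        for j, c in enumerate(pat):
            for b in IUPAC[c]:
                tables[pi, j, _ENCODE[ord(b)]] = True
    return tables


def _scan_strand(codes: np.ndarray, k: int, pam_tables: np.ndarray):
    """Return (starts, keys, pam_codes) of valid sites on one strand.

    ``starts`` are protospacer start offsets on the scanned sequence.
    ``pam_codes`` pack the 3 PAM bases into 6 bits.
    """
    L = codes.shape[0]
    n = L - k - 3 + 1
    if n <= 0:
        z = np.empty(0, dtype=np.int64)
        return z, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint8)
    bad = (codes > 3).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    proto_ok = (cs[k:n + k] - cs[:n]) == 0
    pam_ok = np.zeros(n, dtype=bool)
    for pi in range(pam_tables.shape[0]):
        m = pam_tables[pi, 0][codes[k : k + n]]
        m &= pam_tables[pi, 1][codes[k + 1 : k + 1 + n]]
        m &= pam_tables[pi, 2][codes[k + 2 : k + 2 + n]]
        pam_ok |= m
    ok = proto_ok & pam_ok
    starts = np.nonzero(ok)[0].astype(np.int64)
    keys = encode_kmers(codes, k)[:n][ok]
    pam_codes = (
        (codes[k : k + n][ok].astype(np.uint8) << 4)
        | (codes[k + 1 : k + 1 + n][ok] << 2)
        | codes[k + 2 : k + 2 + n][ok]
    )
    return starts, keys, pam_codes


def _decode_pam(code: int) -> str:
    return "ACGT"[(code >> 4) & 3] + "ACGT"[(code >> 2) & 3] + "ACGT"[code & 3]


class TargetIndex:
    """Sorted-key prefix index over every Cas9 target site in a genome.

    Occurrences are stored grouped by unique protospacer key (CSR layout);
    :meth:`query` performs the depth-first bounded-mismatch traversal.
    """

    FORMAT_VERSION = 1

    def __init__(self, k, pam_patterns, genome_id, chrom_names,
                 keys, indptr, occ_chrom, occ_start, occ_strand, occ_pam):
        self.k = int(k)
        self.pam_patterns = tuple(pam_patterns)
        self.genome_id = str(genome_id)
        self.chrom_names = list(chrom_names)
        self.keys = keys
        self.indptr = indptr
        self.occ_chrom = occ_chrom
        self.occ_start = occ_start
        self.occ_strand = occ_strand
        self.occ_pam = occ_pam

    # -- construction ------------------------------------------------------

    @classmethod
    def build(cls, genome: Mapping[str, str] | str | Path, k: int = 20,
              pam_patterns: Iterable[str] = DEFAULT_PAMS,
              exclude_alt: bool = False,
              alt_pattern: str = DEFAULT_ALT_PATTERN,
              genome_id: str = "custom") -> "TargetIndex":
        if k not in (19, 20):
            raise ValueError(f"protospacer length k must be 19 or 20, got {k}")
        pams = _validate_pams(pam_patterns)
        seqs = _as_genome(genome)
        if exclude_alt:
            alt_re = re.compile(alt_pattern)
            seqs = {n: s for n, s in seqs.items() if not alt_re.search(n)}
        if not seqs or all(len(s) == 0 for s in seqs.values()):
            raise ValueError("empty genome: no sequences to index")

        pam_tables = _pam_lookup(pams)
        chrom_names = list(seqs.keys())
        all_keys, all_chrom, all_start, all_strand, all_pam = [], [], [], [], []
        for ci, (name, seq) in enumerate(seqs.items()):
            L = len(seq)
            codes = encode_sequence(seq)
            starts, keys, pam_codes = _scan_strand(codes, k, pam_tables)
            all_keys.append(keys)
            all_chrom.append(np.full(starts.shape, ci, dtype=np.int32))
            all_start.append(starts)
            all_strand.append(np.zeros(starts.shape, dtype=np.int8))
            all_pam.append(pam_codes)
            # minus strand: scan the reverse complement; offset i there maps
            # to + strand protospacer start L - (i + k)
            rc_codes = encode_sequence(reverse_complement(seq))
            starts, keys, pam_codes = _scan_strand(rc_codes, k, pam_tables)
            all_keys.append(keys)
            all_chrom.append(np.full(starts.shape, ci, dtype=np.int32))
            all_start.append(L - (starts + k))
            all_strand.append(np.ones(starts.shape, dtype=np.int8))
            all_pam.append(pam_codes)

        keys = np.concatenate(all_keys)
        chrom = np.concatenate(all_chrom)
        start = np.concatenate(all_start)
        strand = np.concatenate(all_strand)
        pam = np.concatenate(all_pam)
        order = np.lexsort((strand, start, chrom, keys))
        keys, chrom, start, strand, pam = (
            keys[order], chrom[order], start[order], strand[order], pam[order])
        uniq, first = np.unique(keys, return_index=True)
        indptr = np.concatenate([first, [keys.shape[0]]]).astype(np.int64)
        return cls(k, pams, genome_id, chrom_names,
                   uniq, indptr, chrom, start, strand, pam)

    # -- queries -----------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return int(self.occ_start.shape[0])

    def _query_raw(self, guide: str, max_distance: int):
        if not 0 <= max_distance <= 3:
            raise ValueError(f"max_distance must be in 0..3, got {max_distance}")
        guide = _validate_guide(guide, self.k)
        codes = encode_sequence(guide)
        return query_sorted_keys(self.keys, self.k, codes, max_distance)

    def query(self, guide: str, max_distance: int = 3) -> list[TargetSite]:
        """All target sites within ``max_distance`` substitutions of the
        guide, sorted by (chrom, start, strand)."""
        idx, dist = self._query_raw(guide, max_distance)
        sites = []
        for i, d in zip(idx, dist):
            proto = decode_key(int(self.keys[i]), self.k)
            for j in range(self.indptr[i], self.indptr[i + 1]):
                sites.append(TargetSite(
                    chrom=self.chrom_names[self.occ_chrom[j]],
                    start=int(self.occ_start[j]),
                    strand="+" if self.occ_strand[j] == 0 else "-",
                    protospacer=proto,
                    pam=_decode_pam(int(self.occ_pam[j])),
                    distance=int(d),
                ))
        sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
        return sites

    def neighbor_counts(self, guide: str, max_distance: int = 3) -> NeighborCounts:
        idx, dist = self._query_raw(guide, max_distance)
        h = [0, 0, 0, 0]
        for i, d in zip(idx, dist):
            h[d] += int(self.indptr[i + 1] - self.indptr[i])
        return NeighborCounts(*h)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        header = json.dumps({
            "format": "csc-target-index",
            "version": self.FORMAT_VERSION,
            "k": self.k,
            "pam_patterns": list(self.pam_patterns),
            "genome_id": self.genome_id,
            "chrom_names": self.chrom_names,
        })
        np.savez_compressed(
            path, header=np.frombuffer(header.encode(), dtype=np.uint8),
            keys=self.keys, indptr=self.indptr, occ_chrom=self.occ_chrom,
            occ_start=self.occ_start, occ_strand=self.occ_strand,
            occ_pam=self.occ_pam)

    @classmethod
    def load(cls, path: str | Path) -> "TargetIndex":
        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            if header.get("format") != "csc-target-index":
                raise ValueError(f"{path}: not a target index file")
            return cls(header["k"], header["pam_patterns"], header["genome_id"],
                       header["chrom_names"], z["keys"], z["indptr"],
                       z["occ_chrom"], z["occ_start"], z["occ_strand"],
                       z["occ_pam"])


# -- module-level operations ----------------------------------------------

def build_target_index(genome, k: int = 20, pam_patterns=DEFAULT_PAMS,
                       exclude_alt: bool = False,
                       alt_pattern: str = DEFAULT_ALT_PATTERN,
                       genome_id: str = "custom") -> TargetIndex:
    """Index every PAM-adjacent ACGT-only k-mer on both strands of a genome."""
    return TargetIndex.build(genome, k=k, pam_patterns=pam_patterns,
                             exclude_alt=exclude_alt, alt_pattern=alt_pattern,
                             genome_id=genome_id)


def hamming_neighbors(index: TargetIndex, guide: str,
                      max_distance: int = 3) -> list[TargetSite]:
    return index.query(guide, max_distance=max_distance)


def neighbor_counts(index: TargetIndex, guide: str,
                    max_distance: int = 3) -> NeighborCounts:
    return index.neighbor_counts(guide, max_distance=max_distance)


def brute_force_site_scan(genome, guide, max_distance: int = 3,
                          pam_patterns=DEFAULT_PAMS, force: bool = False):
    """Independent oracle: slide a window over both strands, check the PAM
    against the expanded pattern set, and count mismatches directly.

    ``guide`` may be a single sequence or a list; a list returns
    ``{guide: [TargetSite, ...]}`` computed against windows extracted once.
    Refuses genomes above 50 Mb unless ``force=True``.
    """
    seqs = _as_genome(genome)
    total = sum(len(s) for s in seqs.values())
    if total > _BRUTE_FORCE_SIZE_GUARD and not force:
        raise ValueError(
            f"genome is {total} bp; brute-force scan refuses > "
            f"{_BRUTE_FORCE_SIZE_GUARD} bp without force=True")
    guides = [guide] if isinstance(guide, str) else list(guide)
    if not guides:
        return {}
    k = len(guides[0])
    if k not in (19, 20):
        raise ValueError(f"protospacer length must be 19 or 20, got {k}")
    gmat = np.stack([encode_sequence(_validate_guide(g, k)) for g in guides])
    pam_set = _expand_pams(_validate_pams(pam_patterns))

    hits: dict[str, list[TargetSite]] = {g: [] for g in guides}
    for name, seq in seqs.items():
        L = len(seq)
        for strand, s in (("+", seq.upper()), ("-", reverse_complement(seq).upper())):
            if L < k + 3:
                continue
            codes = encode_sequence(s)
            n = L - k - 2
            wins = np.lib.stride_tricks.sliding_window_view(codes, k)[:n]
            valid = ~(wins > 3).any(axis=1)
            # 6-bit PAM codes checked against the expanded pattern set
            p0 = codes[k : k + n].astype(np.int32)
            p1 = codes[k + 1 : k + 1 + n].astype(np.int32)
            p2 = codes[k + 2 : k + 2 + n].astype(np.int32)
            pam_member = np.zeros(64, dtype=bool)
            for p in pam_set:
                pc = encode_sequence(p)
                pam_member[pc[0] * 16 + pc[1] * 4 + pc[2]] = True
            pam_ok = (p0 <= 3) & (p1 <= 3) & (p2 <= 3)
            pam_code = np.where(pam_ok, p0 * 16 + p1 * 4 + p2, 0)
            pam_valid = pam_ok & pam_member[pam_code]
            keep = np.nonzero(valid & pam_valid)[0]
            if keep.size == 0:
                continue
            wmat = wins[keep]
            for gi, g in enumerate(guides):
                dists = (wmat != gmat[gi]).sum(axis=1)
                for wi in np.nonzero(dists <= max_distance)[0]:
                    i = int(keep[wi])
                    start = i if strand == "+" else L - (i + k)
                    hits[g].append(TargetSite(
                        chrom=name, start=start, strand=strand,
                        protospacer=s[i : i + k], pam=s[i + k : i + k + 3],
                        distance=int(dists[wi])))
    for g in hits:
        hits[g].sort(key=lambda t: (t.chrom, t.start, t.strand))
    return hits[guides[0]] if isinstance(guide, str) else hits


def write_bed(sites: Iterable[TargetSite], path: str | Path,
              name: str | None = None) -> None:
    """BED6 export of enumerated sites (name=guide/protospacer, score=distance)."""
    with open(path, "w") as fh:
        for s in sites:
            label = name if name is not None else s.protospacer
            score = s.distance if s.distance >= 0 else 0
            fh.write(f"{s.chrom}\t{s.start}\t{s.start + len(s.protospacer)}"
                     f"\t{label}\t{score}\t{s.strand}\n")
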