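"""k-mer extraction, 2-bit encoding, and the inverted reference index.

Every sequence is reduced to its *set* of 8-mers. With the fixed word size
k = 8 and a 2-bit alphabet encoding (A=00, C=01, G=10, T=11, first base most
significant) each 8-mer fits a 16-bit unsigned integer, so a k-mer set is a
sorted array of codes in [0, 65536). The reference database is stored as an
inverted index: for each of the 65 536 codes, the sorted list of reference
leaves containing it. Intersection sizes |Q ∩ K_i| between a query set Q and
all references are then obtained by one lookup per query k-mer, costing
O(|Q ∩ K_i|) per pair instead of a full sorted-set merge.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field

import numpy as np

from .lineage import LineageTree, build_lineage_tree

K = 8  # word size; fixed so one k-mer fits a u16
NUM_CODES = 4**K  # 65 536

_BASES = "ACGT"
_BASE_VALUE = {b: v for v, b in enumerate(_BASES)}

# byte -> 2-bit value; 255 marks anything that invalidates a window
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _v in _BASE_VALUE.items():
    _LUT[ord(_b)] = _v
    _LUT[ord(_b.lower())] = _v
# RNA input: U reads as T
_LUT[ord("U")] = _BASE_VALUE["T"]
_LUT[ord("u")] = _BASE_VALUE["T"]

_POWERS = (4 ** np.arange(K - 1, -1, -1)).astype(np.uint32)


class InvalidKmerError(ValueError):
    """Raised when a string cannot be encoded as a single k-mer."""


class IndexBuildError(ValueError):
    """Raised when a reference database cannot be indexed."""


class IndexLoadError(ValueError):
    """Raised when a binary index file is unreadable or incompatible."""


def encode_kmer(kmer: str) -> int:
    """Encode an 8-character ACGT string as a 16-bit integer code.

    The first base occupies the most significant bit pair, so codes sort
    lexicographically with the sequence. Raises :class:`InvalidKmerError`
    for wrong length or non-ACGT characters (``U`` is accepted as ``T``).
    """
    if len(kmer) != K:
        raise InvalidKmerError(f"expected a {K}-mer, got {len(kmer)} characters: {kmer!r}")
    code = 0
    for ch in kmer:
        v = _LUT[ord(ch)] if ord(ch) < 256 else 255
        if v == 255:
            raise InvalidKmerError(f"invalid base {ch!r} in k-mer {kmer!r}")
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    if not 0 <= code < NUM_CODES:
        raise InvalidKmerError(f"code {code} outside [0, {NUM_CODES})")
    out = []
    for shift in range(2 * (K - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


@dataclass(frozen=True)
class KmerSet:
    """Deduplicated, sorted 2-bit codes of the valid 8-mers of one sequence."""

    codes: np.ndarray  # uint32, strictly increasing
    source_length: int

    def __len__(self) -> int:
        return int(self.codes.size)


def _window_codes(sequence: str) -> np.ndarray:
    raw = np.frombuffer(sequence.encode("latin-1", errors="replace"), dtype=np.uint8)
    vals = _LUT[raw]
    windows = np.lib.stride_tricks.sliding_window_view(vals, K)
    valid = (windows != 255).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.uint32)
    return windows[valid].astype(np.uint32) @ _POWERS


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement each 8-mer code (complement = bitwise NOT per pair)."""
    out = np.zeros_like(codes)
    c = (~codes.astype(np.uint32)) & np.uint32(NUM_CODES - 1)
    for _ in range(K):
        out = (out << np.uint32(2)) | (c & np.uint32(3))
        c >>= np.uint32(2)
    return out & np.uint32(NUM_CODES - 1)


def extract_kmer_set(sequence: str, include_revcomp: bool = False) -> KmerSet:
    """Extract the set of valid 8-mers from a DNA sequence.

    Case-insensitive; ``U`` is read as ``T``. Any window overlapping a gap,
    an IUPAC ambiguity code, or any other non-ACGT character is discarded.
    Sequences shorter than 8 yield an empty set. With ``include_revcomp``
    the 8-mers of the reverse-complement strand are added (off by default;
    queries are assumed to be in reference orientation).
    """
    n = len(sequence)
    if n < K:
        return KmerSet(np.empty(0, dtype=np.uint32), n)
    codes = _window_codes(sequence)
    if include_revcomp and codes.size:
        codes = np.concatenate([codes, revcomp_codes(codes)])
    if codes.size == 0:
        return KmerSet(codes, n)
    return KmerSet(np.unique(codes).astype(np.uint32), n)


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference sequence: its identifier, lineage, and |K_i|."""

    ref_id: str
    lineage: tuple[tuple[str, str], ...]  # (rank_label, taxon) high -> low
    kmer_count: int


@dataclass
class ReferenceIndex:
    """Query-independent inverted index over a reference database.

    ``postings[c]`` is the sorted array of reference leaf indices whose k-mer
    set contains code ``c`` (``None`` when empty). ``records`` are stored in
    post-order leaf order of ``tree`` so that clade scores can later be read
    off prefix sums.
    """

    postings: list[np.ndarray | None]
    records: list[ReferenceRecord]
    tree: LineageTree
    format_version: int = 1

    @property
    def n_references(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class IntersectionCounts:
    """Sparse |Q ∩ K_i| per reference; zero intersections are absent."""

    indices: np.ndarray  # reference leaf indices, increasing
    counts: np.ndarray  # positive intersection sizes, aligned with indices
    query_kmer_count: int

    def as_dict(self) -> dict[int, int]:
        return {int(i): int(c) for i, c in zip(self.indices, self.counts)}


def build_reference_index(
    records: list[tuple[str, list[tuple[str, str]], str]],
    include_revcomp: bool = False,
) -> ReferenceIndex:
    """Build the inverted index from ``(ref_id, lineage, sequence)`` triples.

    References are re-ordered to the post-order leaf layout of the lineage
    tree built from all lineages; the build is deterministic and invariant
    to the input order of references.
    """
    if not records:
        raise IndexBuildError("reference database is empty")
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise IndexBuildError(f"duplicate reference ids: {dup[:5]}")

    tree, perm = build_lineage_tree([(r[0], list(r[1])) for r in records])
    # perm[original position] -> post-order leaf index
    ordered: list[tuple[str, list[tuple[str, str]], str] | None] = [None] * len(records)
    for orig, leaf in enumerate(perm):
        ordered[leaf] = records[orig]

    out_records: list[ReferenceRecord] = []
    code_lists: list[list[int]] = [[] for _ in range(NUM_CODES)]
    for leaf, rec in enumerate(ordered):
        assert rec is not None
        ref_id, lin, seq = rec
        kset = extract_kmer_set(seq, include_revcomp=include_revcomp)
        out_records.append(ReferenceRecord(ref_id, tuple((a, b) for a, b in lin), len(kset)))
        for code in kset.codes.tolist():
            code_lists[code].append(leaf)

    postings: list[np.ndarray | None] = [
        np.asarray(lst, dtype=np.uint32) if lst else None for lst in code_lists
    ]
    return ReferenceIndex(postings=postings, records=out_records, tree=tree)


def intersection_counts(index: ReferenceIndex, query: KmerSet) -> IntersectionCounts:
    """Compute |Q ∩ K_i| for every reference with nonzero intersection."""
    hits = [index.postings[c] for c in query.codes.tolist()]
    hits = [h for h in hits if h is not None]
    if not hits:
        return IntersectionCounts(
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), len(query)
        )
    all_hits = np.concatenate(hits)
    counts = np.bincount(all_hits, minlength=index.n_references)
    idx = np.nonzero(counts)[0]
    return IntersectionCounts(idx, counts[idx], len(query))


# ---------------------------------------------------------------------------
# Binary persistence: magic "KMTX", little-endian fixed-width integers,
# postings as delta-encoded varints. Strings are u32-length-prefixed UTF-8.

MAGIC = b"KMTX"
FORMAT_VERSION = 1


def _write_varint(buf: io.BytesIO, value: int) -> None:
    while True:
        b = value & 0x7F
        value >>= 7
        if value:
            buf.write(bytes((b | 0x80,)))
        else:
            buf.write(bytes((b,)))
            return


def _read_varint(data: bytes, pos: int) -> tuple[int, int]:
    result = 0
    shift = 0
    while True:
        if pos >= len(data):
            raise IndexLoadError("truncated index file (varint)")
        b = data[pos]
        pos += 1
        result |= (b & 0x7F) << shift
        if not b & 0x80:
            return result, pos
        shift += 7


def _write_str(buf: io.BytesIO, s: str) -> None:
    raw = s.encode("utf-8")
    buf.write(struct.pack("<I", len(raw)))
    buf.write(raw)


def _read_str(data: bytes, pos: int) -> tuple[str, int]:
    if pos + 4 > len(data):
        raise IndexLoadError("truncated index file (string length)")
    (n,) = struct.unpack_from("<I", data, pos)
    pos += 4
    if pos + n > len(data):
        raise IndexLoadError("truncated index file (string payload)")
    return data[pos : pos + n].decode("utf-8"), pos + n


def save_index(index: ReferenceIndex, path) -> None:
    """Serialize the index to ``path`` in the KMTX binary format."""
    buf = io.BytesIO()
    buf.write(MAGIC)
    buf.write(struct.pack("<I", index.format_version))
    buf.write(struct.pack("<I", len(index.records)))
    for rec in index.records:
        _write_str(buf, rec.ref_id)
        buf.write(struct.pack("<I", len(rec.lineage)))
        for label, name in rec.lineage:
            _write_str(buf, label)
            _write_str(buf, name)
        buf.write(struct.pack("<I", rec.kmer_count))
    for code in range(NUM_CODES):
        plist = index.postings[code]
        if plist is None:
            _write_varint(buf, 0)
            continue
        _write_varint(buf, len(plist))
        prev = 0
        for v in plist.tolist():
            _write_varint(buf, v - prev)
            prev = v
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_index(path) -> ReferenceIndex:
    """Read an index written by :func:`save_index`.

    Raises :class:`IndexLoadError` on bad magic bytes, an unsupported
    format version, or a truncated/corrupt file.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 12:
        raise IndexLoadError("file too short to be a KMTX index")
    if data[:4] != MAGIC:
        raise IndexLoadError(f"bad magic bytes {data[:4]!r}; not a KMTX index")
    (version,) = struct.unpack_from("<I", data, 4)
    if version != FORMAT_VERSION:
        raise IndexLoadError(
            f"unsupported index format version {version} (expected {FORMAT_VERSION})"
        )
    (n_records,) = struct.unpack_from("<I", data, 8)
    pos = 12
    records: list[ReferenceRecord] = []
    lineages: list[tuple[str, list[tuple[str, str]]]] = []
    for _ in range(n_records):
        ref_id, pos = _read_str(data, pos)
        if pos + 4 > len(data):
            raise IndexLoadError("truncated index file (lineage length)")
        (n_ranks,) = struct.unpack_from("<I", data, pos)
        pos += 4
        lin: list[tuple[str, str]] = []
        for _ in range(n_ranks):
            label, pos = _read_str(data, pos)
            name, pos = _read_str(data, pos)
            lin.append((label, name))
        if pos + 4 > len(data):
            raise IndexLoadError("truncated index file (k-mer count)")
        (kcount,) = struct.unpack_from("<I", data, pos)
        pos += 4
        records.append(ReferenceRecord(ref_id, tuple(lin), kcount))
        lineages.append((ref_id, lin))
    postings: list[np.ndarray | None] = [None] * NUM_CODES
    for code in range(NUM_CODES):
        n, pos = _read_varint(data, pos)
        if n == 0:
            continue
        vals = np.empty(n, dtype=np.uint32)
        prev = 0
        for j in range(n):
            d, pos = _read_varint(data, pos)
            prev += d
            vals[j] = prev
        postings[code] = vals
    if pos != len(data):
        raise IndexLoadError("trailing bytes after index payload")
    tree, perm = build_lineage_tree(lineages)
    if any(perm[i] != i for i in range(len(perm))):
        raise IndexLoadError("stored records are not in post-order leaf layout")
    return ReferenceIndex(
        postings=postings, records=records, tree=tree, format_version=version
    )
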