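"""Input parsing, classification orchestration, and tabular output.

The classification pipeline per query: extract the k-mer set, look up
intersection sizes against the inverted index, compute best-match
probabilities, aggregate them over the lineage tree, and attach the two
uncertainty signals. Queries are independent units; output order follows
input order and is byte-identical regardless of worker count.
"""

from __future__ import annotations

import gzip
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .kmers import (
    IntersectionCounts,
    KmerSet,
    ReferenceIndex,
    extract_kmer_set,
    intersection_counts,
)
from .lineage import LineageParseError, LineageResult, aggregate_confidences, parse_lineage
from .match import SamplingParameters, best_match_probabilities
from .uncertainty import global_signal, local_signal_for_result

logger = logging.getLogger("kmertax")


class InputFormatError(ValueError):
    """Raised for unreadable or malformed sequence input files."""


def _open_text(path):
    """Open ``path`` for text reading, transparently gunzipping."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass(frozen=True)
class QueryRecord:
    query_id: str
    sequence: str


def read_reference_fasta(path) -> list[tuple[str, list[tuple[str, str]], str]]:
    """Read a reference FASTA whose headers carry ``tax=`` lineages.

    Returns ``(ref_id, lineage, sequence)`` triples with sequences
    uppercased. Duplicate sequences are retained; deduplication is an
    upstream preprocessing choice.
    """
    out = []
    with _open_text(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fasta")):
            try:
                lin = parse_lineage(rec.description)
            except LineageParseError as exc:
                raise InputFormatError(
                    f"record {i + 1} ({rec.id!r}) in {path}: {exc}"
                ) from exc
            ref_id = rec.description.split(";", 1)[0].strip()
            out.append((ref_id, lin, str(rec.seq).upper()))
    if not out:
        raise InputFormatError(f"no FASTA records in {path}")
    return out


def read_query_sequences(path) -> list[QueryRecord]:
    """Read queries from FASTA or FASTQ (auto-detected by the first byte).

    FASTQ qualities are ignored; input order is preserved. Duplicate query
    ids are suffixed ``.2``, ``.3``, … deterministically, with a warning.
    """
    with _open_text(path) as fh:
        head = fh.read(1)
        fh.seek(0)
        if head == ">":
            fmt = "fasta"
        elif head == "@":
            fmt = "fastq"
        else:
            raise InputFormatError(
                f"{path}: first byte {head!r} is neither FASTA '>' nor FASTQ '@'"
            )
        try:
            records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]
        except ValueError as exc:
            raise InputFormatError(f"{path}: malformed {fmt.upper()}: {exc}") from exc
    if not records:
        raise InputFormatError(f"no sequence records in {path}")
    seen: dict[str, int] = {}
    out: list[QueryRecord] = []
    for qid, seq in records:
        n = seen.get(qid, 0) + 1
        seen[qid] = n
        if n > 1:
            logger.warning("duplicate query id %s renamed to %s.%d", qid, qid, n)
            qid = f"{qid}.{n}"
        out.append(QueryRecord(qid, seq))
    return out


@dataclass(frozen=True)
class ClassificationRow:
    """One reported lineage for one query (or its unclassified marker)."""

    query_id: str
    result: LineageResult | None
    confidence: float
    local_signal: float
    global_signal: float
    status: str  # "classified" | "unclassified"


def _classify_one(
    query: QueryRecord,
    index: ReferenceIndex,
    t: int,
    prune_threshold: float,
    pool: str,
    revcomp: bool,
    kmer_counts: np.ndarray,
) -> list[ClassificationRow]:
    def unclassified() -> list[ClassificationRow]:
        return [ClassificationRow(query.query_id, None, 0.0, 0.0, 0.0, "unclassified")]

    kset = extract_kmer_set(query.sequence, include_revcomp=revcomp)
    if len(kset) == 0:
        return unclassified()
    inter = intersection_counts(index, kset)
    if inter.indices.size == 0:
        return unclassified()
    params = SamplingParameters(t=t, query_kmer_count=len(kset))
    bmp = best_match_probabilities(
        inter, params, pool=pool, reference_kmer_counts=kmer_counts
    )
    if bmp is None:
        return unclassified()
    n = index.n_references
    dense = np.zeros(n, dtype=np.float64)
    dense[bmp.indices] = bmp.confidence
    results = aggregate_confidences(index.tree, dense, prune_threshold)
    if not results:
        return unclassified()
    sg = global_signal(bmp.confidence, n)
    rows = []
    for res in results:
        sl = local_signal_for_result(res, n)
        rows.append(
            ClassificationRow(
                query.query_id, res, res.terminal_score, sl, sg, "classified"
            )
        )
    return rows


def classify(
    index: ReferenceIndex,
    queries: list[QueryRecord],
    t: int = 32,
    prune_threshold: float = 0.005,
    *,
    min_confidence: float = 0.0,
    threads: int = 1,
    pool: str = "query",
    revcomp: bool = False,
) -> list[ClassificationRow]:
    """Classify queries against the index; rows grouped per query, best first.

    ``min_confidence`` filters reported lineages at report time only (a
    query whose every lineage is filtered falls back to an unclassified
    row); it never alters computed scores. ``threads`` parallelizes over
    queries with order-stable results.
    """
    kmer_counts = np.asarray([r.kmer_count for r in index.records], dtype=np.int64)

    done = 0

    def work(q: QueryRecord) -> list[ClassificationRow]:
        nonlocal done
        rows = _classify_one(q, index, t, prune_threshold, pool, revcomp, kmer_counts)
        done += 1
        if done % 1000 == 0:
            logger.info("classified %d/%d queries", done, len(queries))
        return rows

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as ex:
            per_query = list(ex.map(work, queries))
    else:
        per_query = [work(q) for q in queries]

    out: list[ClassificationRow] = []
    for q, rows in zip(queries, per_query):
        if min_confidence > 0.0:
            kept = [r for r in rows if r.status != "classified" or r.confidence >= min_confidence]
            if not kept:
                kept = [ClassificationRow(q.query_id, None, 0.0, 0.0, 0.0, "unclassified")]
            rows = kept
        out.extend(rows)
    return out


RESULT_COLUMNS = (
    "query_id",
    "lineage",
    "confidence",
    "local_signal",
    "global_signal",
    "status",
)


def write_results(rows: list[ClassificationRow], path, *, percent: bool = False) -> None:
    """Write classification rows as a deterministic TSV.

    Scores are printed with fixed 4-decimal notation (×100 when ``percent``
    is set, matching the 0–100 confidence-cutoff convention); lines end in
    LF and the file is UTF-8.
    """
    scale = 100.0 if percent else 1.0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in rows:
            lineage = row.result.lineage_string(percent=percent) if row.result else ""
            fh.write(
                "\t".join(
                    (
                        row.query_id,
                        lineage,
                        f"{row.confidence * scale:.4f}",
                        f"{row.local_signal:.4f}",
                        f"{row.global_signal:.4f}",
                        row.status,
                    )
                )
                + "\n"
            )
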