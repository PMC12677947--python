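"""Seeded synthetic reference databases, mutated queries, and F1 evaluation.

The generator emulates the structure a barcode classifier faces in practice:
a hierarchical taxonomy with uneven clade sizes (one over-represented
family), reference sequences that are random DNA with within-species
similarity, and queries that are point-mutated (optionally indel-bearing)
copies of references. Everything is deterministic under the configured seed.

The evaluation side implements the confidence-cutoff protocol: every result
below a cutoff is labelled "not classified", a wrong taxon at-or-above the
cutoff counts as misclassified (entering the recall denominator), and
recall/precision/F1 are computed per rank and cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ClassificationRow

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationConfigError(ValueError):
    """Raised for impossible simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic database and query generator.

    Defaults describe the biased-database scenario: 8 families, one of which
    holds 50% of the leaves (imbalance factor 7 → 42 vs 6 genera), 6 species
    per genus, one 300 bp sequence per species (504 references total),
    queries mutated at a 2% per-base substitution rate.
    """

    seed: int = 42
    ranks: tuple[tuple[str, int], ...] = (("f", 8), ("g", 6), ("s", 6))
    n_sequences_per_species: int = 1
    seq_length: int = 300
    within_species_divergence: float = 0.01
    query_mutation_rate: float = 0.02
    query_indel_rate: float = 0.0
    n_queries_per_reference: int = 1
    clade_imbalance: float = 7.0

    def __post_init__(self) -> None:
        if not self.ranks or any(c < 1 for _, c in self.ranks):
            raise SimulationConfigError("ranks must be non-empty with counts >= 1")
        if self.n_sequences_per_species < 1:
            raise SimulationConfigError("need at least one sequence per species")
        if self.seq_length < 8:
            raise SimulationConfigError("sequences must be at least one k-mer long")
        for name in ("within_species_divergence", "query_mutation_rate", "query_indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise SimulationConfigError(f"{name}={v} outside [0, 1)")
        if self.clade_imbalance < 1.0:
            raise SimulationConfigError("clade_imbalance must be >= 1")


def _taxonomy_paths(config: SimulationConfig) -> list[list[tuple[str, str]]]:
    """Enumerate the lineage of every species, applying the imbalance skew.

    The first clade of the top rank receives ``round(imbalance × c)``
    children at the next rank instead of ``c``; with the defaults that makes
    its leaf share exactly imbalance / (imbalance + n_top − 1).
    """
    paths: list[list[tuple[str, str]]] = [[]]
    for depth, (label, count) in enumerate(config.ranks):
        new_paths = []
        for path in paths:
            n_children = count
            first_top = config.ranks[0][0].upper() + "1"
            if depth == 1 and path and path[0][1] == first_top:
                n_children = int(round(config.clade_imbalance * count))
            prefix = path[-1][1] + "_" if path else ""
            for i in range(1, n_children + 1):
                new_paths.append(path + [(label, f"{prefix}{label.upper()}{i}")])
        paths = new_paths
    return paths


def _mutate(
    seq: np.ndarray, rng: np.random.Generator, sub_rate: float, indel_rate: float
) -> np.ndarray:
    """Apply per-base substitutions and (optionally) single-base indels."""
    out = seq.copy()
    if sub_rate > 0:
        hit = rng.random(out.size) < sub_rate
        n_hit = int(hit.sum())
        if n_hit:
            # substitute with one of the three other bases
            shift = rng.integers(1, 4, size=n_hit)
            cur = np.searchsorted(_BASES, out[hit])
            out[hit] = _BASES[(cur + shift) % 4]
    if indel_rate > 0:
        keep_parts = []
        i = 0
        events = np.nonzero(rng.random(out.size) < indel_rate)[0]
        for pos in events:
            keep_parts.append(out[i:pos])
            if rng.random() < 0.5:
                i = pos + 1  # deletion
            else:
                keep_parts.append(out[pos : pos + 1])
                keep_parts.append(_BASES[rng.integers(0, 4, size=1)])  # insertion
                i = pos + 1
        keep_parts.append(out[i:])
        out = np.concatenate(keep_parts)
    return out


def generate_database(
    config: SimulationConfig,
) -> list[tuple[str, list[tuple[str, str]], str]]:
    """Generate ``(ref_id, lineage, sequence)`` triples for the taxonomy.

    Each species draws a random ancestor sequence; its references are copies
    of that ancestor mutated at the within-species divergence rate.
    Deterministic: the same config always yields identical records.
    """
    rng = np.random.default_rng([config.seed, 0])
    records = []
    counter = 0
    for path in _taxonomy_paths(config):
        ancestor = _BASES[rng.integers(0, 4, size=config.seq_length)]
        for _ in range(config.n_sequences_per_species):
            counter += 1
            seq = _mutate(ancestor, rng, config.within_species_divergence, 0.0)
            records.append((f"R{counter:05d}", list(path), seq.tobytes().decode("ascii")))
    return records


def generate_queries(
    records: list[tuple[str, list[tuple[str, str]], str]],
    config: SimulationConfig,
    n_queries: int | None = None,
) -> list[tuple[str, list[tuple[str, str]], str]]:
    """Generate ``(query_id, true_lineage, sequence)`` mutated query copies.

    By default every reference spawns ``n_queries_per_reference`` queries;
    with ``n_queries`` set, that many source references are sampled (without
    replacement when possible). Substitutions and indels are applied at the
    configured rates; the truth records the source reference's lineage.
    """
    rng = np.random.default_rng([config.seed, 1])
    if n_queries is None:
        sources = [i for i in range(len(records)) for _ in range(config.n_queries_per_reference)]
    else:
        replace = n_queries > len(records)
        sources = sorted(
            rng.choice(len(records), size=n_queries, replace=replace).tolist()
        )
    queries = []
    for qnum, src in enumerate(sources, start=1):
        ref_id, lineage, seq = records[src]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        mut = _mutate(arr, rng, config.query_mutation_rate, config.query_indel_rate)
        queries.append(
            (f"Q{qnum:05d}_{ref_id}", list(lineage), mut.tobytes().decode("ascii"))
        )
    return queries


def write_fasta(records, path, *, with_tax: bool) -> None:
    """Write records as FASTA; with ``with_tax`` the header carries the
    ``;tax=...;`` lineage annotation."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, lineage, seq in records:
            if with_tax:
                tax = ",".join(f"{label}:{taxon}" for label, taxon in lineage)
                fh.write(f">{name};tax={tax};\n")
            else:
                fh.write(f">{name}\n")
            fh.write(seq + "\n")


def write_truth(records, path) -> None:
    """Write the query→lineage truth table as TSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("query_id\tlineage\n")
        for name, lineage, _ in records:
            fh.write(name + "\t" + ",".join(f"{l}:{t}" for l, t in lineage) + "\n")


def cross_validation_split(
    records: list, fold_count: int, seed: int
) -> list[tuple[list, list]]:
    """Split records into ``fold_count`` (reference, query) folds.

    Query subsets partition the records with sizes differing by at most one
    (10 folds → the 90/10 protocol); deterministic under ``seed``.
    """
    if fold_count < 2:
        raise SimulationConfigError("fold_count must be >= 2")
    if len(records) < fold_count:
        raise SimulationConfigError(
            f"{len(records)} records cannot form {fold_count} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    groups = np.array_split(order, fold_count)
    folds = []
    for g in groups:
        qset = set(g.tolist())
        queries = [records[i] for i in sorted(qset)]
        refs = [records[i] for i in range(len(records)) if i not in qset]
        folds.append((refs, queries))
    return folds


# ---------------------------------------------------------------------------
# Confidence-cutoff evaluation


@dataclass(frozen=True)
class EvaluationRow:
    """Counts and scores for one rank at one confidence cutoff (0–100)."""

    rank: str
    cutoff: float
    tp: int
    mc: int
    fn: int
    fp: int
    recall: float
    precision: float
    f1: float
    precision_undefined: bool = False


@dataclass
class EvaluationTable:
    rows: list[EvaluationRow] = field(default_factory=list)


def predictions_from_rows(
    rows: list[ClassificationRow],
) -> dict[str, dict[str, tuple[str, float]]]:
    """Top-lineage per-rank predictions on the 0–100 confidence scale.

    For each query the first (best) reported lineage supplies, per rank
    label, the predicted taxon and its clade confidence ×100. Unclassified
    queries map to an empty dict.
    """
    preds: dict[str, dict[str, tuple[str, float]]] = {}
    for row in rows:
        if row.query_id in preds:
            continue  # rows for one query are contiguous, best lineage first
        per_rank: dict[str, tuple[str, float]] = {}
        if row.result is not None:
            for clade in row.result.clades:
                if clade.rank_label:
                    per_rank[clade.rank_label] = (clade.taxon_name, clade.score * 100.0)
        preds[row.query_id] = per_rank
    return preds


def evaluate_f1(
    predictions: dict[str, dict[str, tuple[str, float]]],
    truths: dict[str, dict[str, str]],
    rank: str,
    cutoffs=range(0, 101),
    *,
    scorable: set[str] | None = None,
) -> EvaluationTable:
    """Tabulate TP/MC/FN/FP and recall/precision/F1 per confidence cutoff.

    At cutoff c: TP = correct taxon with confidence ≥ c; MC = FP = wrong
    taxon with confidence ≥ c; FN = below-cutoff (treated as "not
    classified"), including queries with no prediction at this rank.
    Recall = TP/(TP+MC+FN); Precision = TP/(TP+FP), reported as 0 and
    flagged when no query is classified. ``scorable`` restricts scoring to
    queries whose true taxon exists in the reference (cross-validation
    bookkeeping); others are skipped at this rank.
    """
    table = EvaluationTable()
    items = []
    for qid, per_rank in predictions.items():
        if qid not in truths:
            raise KeyError(f"query {qid!r} has predictions but no truth entry")
        if scorable is not None and qid not in scorable:
            continue
        truth_taxon = truths[qid].get(rank)
        if truth_taxon is None:
            continue
        items.append((per_rank.get(rank), truth_taxon))
    for cutoff in cutoffs:
        tp = mc = fn = 0
        for pred, truth_taxon in items:
            if pred is None or pred[1] < cutoff:
                fn += 1
            elif pred[0] == truth_taxon:
                tp += 1
            else:
                mc += 1
        fp = mc  # under this protocol a misclassification is the only FP source
        denom_r = tp + mc + fn
        recall = tp / denom_r if denom_r else 0.0
        undefined = (tp + fp) == 0
        precision = 0.0 if undefined else tp / (tp + fp)
        f1 = (
            2 * recall * precision / (recall + precision)
            if (recall + precision) > 0
            else 0.0
        )
        table.rows.append(
            EvaluationRow(rank, float(cutoff), tp, mc, fn, fp, recall, precision, f1, undefined)
        )
    return table


def truths_from_records(queries) -> dict[str, dict[str, str]]:
    """Truth lookup ``query_id → {rank_label: taxon}`` from query triples."""
    return {qid: {l: t for l, t in lineage} for qid, lineage, _ in queries}
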