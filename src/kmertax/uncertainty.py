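"""Database-bias-aware uncertainty scores for an assignment.

Reference databases are taxonomically uneven: if one family holds half the
references, half the confidence mass lands there by composition alone. The
expectation for a query that resembles nothing in particular is therefore
the uniform per-reference vector P̄ = (1/n, …, 1/n), which induces a clade
expectation L̄(B) = |B|/n. Two Euclidean distances from that expectation are
reported raw (no rescaling): the local signal per reported lineage and the
global signal per query. Zero means "indistinguishable from database bias";
larger values mean the data moved the assignment away from it.
"""

from __future__ import annotations

import math

import numpy as np

from .lineage import LineageResult


class InvalidSignalInputError(ValueError):
    """Raised for degenerate inputs to the signal computations."""


def local_signal(observed, expected) -> float:
    """Euclidean distance between L1-normalized observed and expected
    per-rank confidence vectors (the per-lineage assignment signal s_l)."""
    obs = np.asarray(observed, dtype=np.float64)
    exp = np.asarray(expected, dtype=np.float64)
    if obs.shape != exp.shape or obs.ndim != 1 or obs.size == 0:
        raise InvalidSignalInputError(
            f"observed/expected shapes {obs.shape}/{exp.shape} invalid"
        )
    if (obs < 0).any() or (exp < 0).any():
        raise InvalidSignalInputError("confidence vectors must be non-negative")
    no, ne = obs.sum(), exp.sum()
    if no <= 0 or ne <= 0:
        raise InvalidSignalInputError("zero-norm confidence vector")
    return float(np.linalg.norm(obs / no - exp / ne))


def local_signal_for_result(result: LineageResult, n_references: int) -> float:
    """s_l of one reported lineage against the database-bias expectation.

    The expected score of each clade on the lineage is its leaf share
    |B|/n; the terminal per-sequence level has expectation 1/n.
    """
    observed = [c.score for c in result.clades]
    expected = [c.leaf_count / n_references for c in result.clades]
    return local_signal(observed, expected)


def global_signal(
    candidate_confidence: np.ndarray, n_references: int
) -> float:
    """s_g = ‖P − P̄‖₂ with implicit zeros for non-candidate references.

    ``candidate_confidence`` holds the L1-normalized confidences of the
    candidate references only; the n − #candidates references outside the
    candidate set carry confidence 0 and contribute (1/n)² each, summed in
    closed form rather than materializing a dense length-n vector.
    """
    if n_references < 1:
        raise InvalidSignalInputError("n_references must be >= 1")
    conf = np.asarray(candidate_confidence, dtype=np.float64)
    k = conf.size
    if k > n_references:
        raise InvalidSignalInputError("more candidates than references")
    u = 1.0 / n_references
    ss = float(np.sum((conf - u) ** 2)) + (n_references - k) * u * u
    return math.sqrt(max(ss, 0.0))
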