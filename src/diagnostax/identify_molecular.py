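"""Placement of raw query sequences into reference coordinates and
identification against diagnosis profiles.

Queries are assumed forward-strand barcodes: no reverse-complement or
reading-frame search is performed.  A query is globally aligned
(Needleman-Wunsch, match +1 / mismatch -1 / linear gap -2) against the
majority-rule consensus of the reference alignment; the resulting column
mapping is then used to test each diagnostic region of each species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostics import Diagnosis, states_compatible
from .msa_io import Alignment, normalize_residues

__all__ = [
    "MATCH",
    "MISMATCH",
    "GAP",
    "MIN_QUERY_LENGTH",
    "CoordinateMap",
    "SpeciesScore",
    "IdentificationResult",
    "consensus_sequence",
    "align_query_to_coords",
    "identify_query",
    "p_distance_matrix",
    "cluster_by_threshold",
]

MATCH = 1
MISMATCH = -1
GAP = -2
MIN_QUERY_LENGTH = 50

# Alphabetical consensus tie-break order; '-' loses every tie.
_CONSENSUS_ORDER = "ACGT-"


@dataclass(frozen=True)
class CoordinateMap:
    """Partial mapping of 1-based query positions onto reference columns."""

    query_id: str
    mapping: dict[int, int]
    score: int

    def __post_init__(self) -> None:
        cols = [self.mapping[p] for p in sorted(self.mapping)]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("coordinate map must be strictly increasing")

    def column_to_query(self) -> dict[int, int]:
        return {col: pos for pos, col in self.mapping.items()}


@dataclass(frozen=True)
class SpeciesScore:
    species: str
    regions_matched: int
    regions_total: int
    #: (region index, column, expected, observed-or-None-if-unmapped)
    mismatches: tuple[tuple[int, int, str, str | None], ...] = ()

    @property
    def full_match(self) -> bool:
        return self.regions_matched == self.regions_total


@dataclass(frozen=True)
class IdentificationResult:
    query_id: str
    scores: tuple[SpeciesScore, ...]
    verdict: str  # "assigned" | "ambiguous" | "unassigned"
    assigned_to: tuple[str, ...] = ()

    def score_for(self, species: str) -> SpeciesScore:
        for s in self.scores:
            if s.species == species:
                return s
        raise KeyError(species)


def consensus_sequence(reference: Alignment) -> str:
    """Majority-rule consensus; ties broken alphabetically (A<C<G<T<'-').

    Gap-majority columns are kept with consensus state ``-`` so that column
    numbering is preserved.  Ambiguity codes vote for ``N``-free purposes as
    themselves and only ``A/C/G/T/-`` can win a column (other symbols are
    counted but never selected; if only ambiguity codes occur the column
    falls back to ``-``).
    """
    cons = []
    for col in range(1, reference.length + 1):
        states = reference.column(col)
        counts = {c: states.count(c) for c in set(states)}
        best, best_count = "-", -1
        for symbol in _CONSENSUS_ORDER:
            count = counts.get(symbol, 0)
            if count > best_count:
                best, best_count = symbol, count
        cons.append(best if best_count > 0 else "-")
    return "".join(cons)


def _nw_matrix(query: str, cons: str) -> np.ndarray:
    """Forward DP matrix; rows index query prefix, cols consensus prefix.

    The in-row (left) dependency under a linear gap penalty reduces to a
    running maximum, which lets each row be computed vectorised.
    """
    n, m = len(query), len(cons)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    c = np.frombuffer(cons.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0, :] = GAP * np.arange(m + 1)
    offsets = -GAP * np.arange(1, m + 1)  # positive ramp, GAP < 0
    for i in range(1, n + 1):
        sub = np.where(c == q[i - 1], MATCH, MISMATCH).astype(np.int32)
        best = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + GAP)
        first = H[i - 1, 0] + GAP  # H[i, 0]
        H[i, 0] = first
        # H[i, j] = max(best[j-1], H[i, j-1] + GAP); the left-chain unrolls
        # to a prefix maximum over (best + offsets).
        ramp = np.maximum.accumulate(np.concatenate(([first], best + offsets)))
        H[i, 1:] = ramp[1:] - offsets
    return H


def align_query_to_coords(
    query: str, reference: Alignment, query_id: str = "query"
) -> CoordinateMap:
    """Global DP alignment of a raw query against the reference consensus.

    Returns the mapping of query positions (1-based) to reference columns.
    Deterministic traceback prefers diagonal, then up (consume a query
    character), then left (skip a consensus column).  Queries shorter than
    ``MIN_QUERY_LENGTH`` are rejected: fragments are unsupported.
    """
    query = normalize_residues(query).replace("-", "")
    if len(query) < MIN_QUERY_LENGTH:
        raise ValueError(
            f"query length {len(query)} below minimum {MIN_QUERY_LENGTH}; "
            "fragment identification is unsupported"
        )
    cons = consensus_sequence(reference)
    H = _nw_matrix(query, cons)

    mapping: dict[int, int] = {}
    i, j = len(query), len(cons)
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = MATCH if query[i - 1] == cons[j - 1] else MISMATCH
            if H[i, j] == H[i - 1, j - 1] + sub:
                mapping[i] = j
                i, j = i - 1, j - 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + GAP:
            i -= 1  # query position left unmapped
            continue
        j -= 1
    return CoordinateMap(query_id=query_id, mapping=mapping, score=int(H[-1, -1]))


def identify_query(
    query: str,
    profiles: Sequence[Diagnosis],
    reference: Alignment,
    query_id: str = "query",
) -> IdentificationResult:
    """Identify a raw query sequence against diagnosis profiles.

    A region is matched iff every one of its columns maps from the query
    and the query state is compatible with the motif state (query ambiguity
    codes compatible with the motif count as matches; an unmapped column
    counts as a mismatch-by-absence).  The verdict is ``assigned`` iff
    exactly one species matches all of its regions.
    """
    if not profiles:
        raise ValueError("profiles must be nonempty")
    for diagnosis in profiles:
        for region in diagnosis.regions:
            if region.end > reference.length:
                raise ValueError(
                    f"region {region.start}-{region.end} of {diagnosis.species!r} "
                    f"outside reference of length {reference.length}"
                )

    query_norm = normalize_residues(query).replace("-", "")
    coord_map = align_query_to_coords(query_norm, reference, query_id=query_id)
    col2q = coord_map.column_to_query()

    scores = []
    for diagnosis in profiles:
        matched = 0
        mismatches: list[tuple[int, int, str, str | None]] = []
        for ridx, region in enumerate(diagnosis.regions):
            ok = True
            for col in region.columns:
                expected = region.motif_at(col)
                qpos = col2q.get(col)
                if qpos is None:
                    mismatches.append((ridx, col, expected, None))
                    ok = False
                elif not states_compatible(query_norm[qpos - 1], expected):
                    mismatches.append((ridx, col, expected, query_norm[qpos - 1]))
                    ok = False
            if ok:
                matched += 1
        scores.append(
            SpeciesScore(
                species=diagnosis.species,
                regions_matched=matched,
                regions_total=len(diagnosis.regions),
                mismatches=tuple(mismatches),
            )
        )

    full = tuple(s.species for s in scores if s.full_match and s.regions_total > 0)
    if len(full) == 1:
        verdict = "assigned"
    elif len(full) > 1:
        verdict = "ambiguous"
    else:
        verdict = "unassigned"
    return IdentificationResult(
        query_id=query_id, scores=tuple(scores), verdict=verdict, assigned_to=full
    )


def p_distance_matrix(alignment: Alignment) -> pd.DataFrame:
    """Pairwise uncorrected p-distance over shared ``A/C/G/T`` columns.

    Pairs with zero comparable columns get ``NaN``.  Symmetric with a zero
    diagonal.
    """
    if len(alignment) < 2:
        raise ValueError("p-distance requires at least two sequences")
    ids = list(alignment.ids)
    arr = np.array([list(s.residues) for s in alignment])
    concrete = np.isin(arr, list("ACGT"))
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = concrete[i] & concrete[j]
            total = int(comparable.sum())
            if total == 0:
                out[i, j] = out[j, i] = np.nan
            else:
                diffs = int((arr[i][comparable] != arr[j][comparable]).sum())
                out[i, j] = out[j, i] = diffs / total
    return pd.DataFrame(out, index=ids, columns=ids)


def cluster_by_threshold(matrix: pd.DataFrame, threshold: float = 0.04) -> list[list[str]]:
    """Single-linkage components at ``threshold`` (edge iff distance < t).

    Clusters are returned sorted by their smallest member id, members
    sorted within each cluster; the result is invariant to input order.
    Missing distances raise an error naming the offending pairs.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    ids = list(matrix.index)
    values = matrix.to_numpy()
    missing = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if np.isnan(values[i, j])
    ]
    if missing:
        raise ValueError(f"missing distances for pairs: {missing}")

    parent = list(range(len(ids)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if values[i, j] < threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[str]] = {}
    for idx, seq_id in enumerate(ids):
        groups.setdefault(find(idx), []).append(seq_id)
    clusters = [sorted(members) for members in groups.values()]
    return sorted(clusters, key=lambda c: c[0])
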