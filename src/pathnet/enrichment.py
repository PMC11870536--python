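"""Standard and dynamic over-representation analysis.

Standard enrichment is the right-tailed Fisher's exact test: for a term
annotated with K of the N universe genes and a dataset contributing n
analyzed genes of which k fall into the term, the p-value is the
hypergeometric upper tail P(X >= k).  The universe N is the ontology's
annotated genes, intersected with the dataset's experimental background
when one is supplied.

Dynamic enrichment additionally merges pairs and triples of functionally
interacting same-level SCPs — each containing at least one analyzed gene —
into dataset-selective terms, tests them alongside the originals, and
splits each significant merged term's -log10(p) equally among its members,
summing multiple contributions per SCP.

Significance uses two per-level cutoffs, maximum p-value and maximum rank
(competition ranking, ties share the smaller rank); a term is significant
only if it meets both.  No multiple-testing correction enters the
significance call; a Benjamini-Hochberg column is emitted in the results
table as supplementary output only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

from pathnet.datasets import Dataset
from pathnet.errors import ParameterError
from pathnet.ontology import (
    InteractionNetwork,
    Ontology,
    merged_scp_id,
    top_percent_interactions,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyCounts:
    """Counts of a 2x2 overlap table.

    k: dataset genes in the term; n: analyzed dataset genes in the
    universe; K: term genes in the universe; N: universe size.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ParameterError(
                f"invalid counts: need 0 <= k <= min(n, K), got {self}"
            )
        if self.n > self.N or self.K > self.N:
            raise ParameterError(
                f"invalid counts: need n <= N and K <= N, got {self}"
            )


def _log_comb(n, r):
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def fisher_right_tail(counts: ContingencyCounts) -> float:
    """Right-tailed Fisher's exact test: P(X >= k), X ~ Hypergeom(N, K, n).

    The leading tail term P(X = k) is evaluated with exact integer
    binomial coefficients (correctly rounded on conversion) and the rest
    of the tail follows from the hypergeometric ratio recurrence, keeping
    the relative error near machine precision for any universe size.
    When the leading term underflows the double range the sum falls back
    to log space (log-gamma + logsumexp).  Returns a value in (0, 1];
    k = 0 gives exactly 1.
    """
    k, n, K, N = counts.k, counts.n, counts.K, counts.N
    if k == 0:
        return 1.0
    hi = min(n, K)
    # leading term P(X = k), correctly rounded via exact integer binomials
    lead = (math.comb(K, k) * math.comb(N - K, n - k)) / math.comb(N, n)
    if lead == 0.0:
        # leading term below float range: accumulate in log space instead
        j = np.arange(k, hi + 1)
        log_terms = _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
        return min(float(np.exp(logsumexp(log_terms))), 1.0)
    # remaining terms by the exact rational recurrence
    # P(X = j+1) / P(X = j) = (K - j)(n - j) / ((j + 1)(N - K - n + j + 1))
    p = term = lead
    for j in range(k, hi):
        term *= (K - j) * (n - j) / ((j + 1) * (N - K - n + j + 1))
        p += term
    return min(p, 1.0)


def _log10_p(p: float) -> float:
    if p <= 0.0:
        # p underflowed the double range; clamp at the smallest subnormal
        return -math.log10(5e-324)
    return -math.log10(p)


@dataclass
class EnrichmentResult:
    """Outcome of one (dataset, term) test.

    For standard results ``minus_log10_p`` is -log10 of the term's own
    p-value; for per-SCP dynamic results it is the summed split value (see
    :func:`split_dynamic`).  ``member_ids`` is non-empty only for merged
    terms in the combined dynamic ranking.
    """

    dataset_name: str
    term_id: str
    counts: ContingencyCounts
    p_value: float
    minus_log10_p: float
    overlap_genes: set[str] = field(default_factory=set)
    level: Optional[int] = None
    rank: int = 0
    significant: bool = False
    source: str = "standard"  # standard | dynamic
    contributing_merged_ids: set[str] = field(default_factory=set)
    member_ids: tuple[str, ...] = ()
    term_name: str = ""


@dataclass(frozen=True)
class MergedSCP:
    """A dataset-selective merged term: 2-3 interacting same-level SCPs."""

    merged_id: str
    member_ids: tuple[str, ...]
    genes: frozenset[str]
    level: Optional[int] = None


@dataclass
class LevelCutoffs:
    """Per-level significance cutoffs: maximum p-value and maximum rank.

    ``per_level`` overrides the defaults for specific levels; level-less
    ontologies use the defaults throughout.  A term is significant iff
    p <= max_p AND rank <= max_rank at its level.
    """

    max_p: float = 0.05
    max_rank: int = 5
    per_level: dict[int, tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self):
        for p, r in [(self.max_p, self.max_rank), *self.per_level.values()]:
            if not (0 < p <= 1):
                raise ParameterError(f"max_p must be in (0, 1], got {p}")
            if r < 1:
                raise ParameterError(f"max_rank must be >= 1, got {r}")

    @classmethod
    def from_lists(
        cls,
        max_p: Sequence[float],
        max_rank: Sequence[int],
        first_level: int = 1,
    ) -> "LevelCutoffs":
        """Cutoffs per level from parallel lists starting at ``first_level``."""
        if len(max_p) != len(max_rank):
            raise ParameterError("max_p and max_rank lists must have equal length")
        per_level = {
            first_level + i: (float(p), int(r))
            for i, (p, r) in enumerate(zip(max_p, max_rank))
        }
        return cls(per_level=per_level)

    def for_level(self, level: Optional[int]) -> tuple[float, int]:
        if level is not None and level in self.per_level:
            return self.per_level[level]
        return (self.max_p, self.max_rank)


# ---------------------------------------------------------------------------
# universe and standard analysis
# ---------------------------------------------------------------------------

def build_universe(
    dataset: Dataset, ontology: Ontology
) -> tuple[set[str], set[str]]:
    """Derive the test universe and the analyzed gene set for one dataset.

    universe = background ∩ annotated genes when a background is attached,
    else the ontology's annotated genes; analyzed = dataset genes ∩ universe.
    """
    annotated = ontology.annotated_universe
    if dataset.background is not None:
        universe = dataset.background & annotated
        n_bg_dropped = len(dataset.background) - len(universe)
        if n_bg_dropped:
            logger.info(
                "dataset %s: %d background genes not annotated in the ontology",
                dataset.name, n_bg_dropped,
            )
    else:
        universe = annotated
    analyzed = dataset.genes & universe
    dropped = len(dataset.genes) - len(analyzed)
    if dropped:
        logger.info(
            "dataset %s: %d of %d genes outside the universe, excluded",
            dataset.name, dropped, len(dataset.genes),
        )
    if not analyzed:
        raise ParameterError(
            f"no dataset genes in universe for dataset {dataset.name!r}"
        )
    return universe, analyzed


def _level_sort_key(level: Optional[int]) -> int:
    return level if level is not None else 0


def standard_enrichment(
    dataset: Dataset, ontology: Ontology
) -> list[EnrichmentResult]:
    """Fisher's exact test of the dataset against every ontology term.

    Terms with no overlap (k = 0) are omitted.  Results are sorted by level,
    then ascending p, then term id.  Ranks and significance flags are
    assigned separately by :func:`rank_and_flag`.
    """
    universe, analyzed = build_universe(dataset, ontology)
    n = len(analyzed)
    N = len(universe)
    results = []
    for term in ontology.terms.values():
        term_genes = term.genes & universe
        overlap = term_genes & analyzed
        if not overlap:
            continue
        counts = ContingencyCounts(k=len(overlap), n=n, K=len(term_genes), N=N)
        p = fisher_right_tail(counts)
        results.append(
            EnrichmentResult(
                dataset_name=dataset.name,
                term_id=term.term_id,
                term_name=term.name,
                counts=counts,
                p_value=p,
                minus_log10_p=_log10_p(p),
                overlap_genes=overlap,
                level=term.level,
                source="standard",
            )
        )
    results.sort(key=lambda r: (_level_sort_key(r.level), r.p_value, r.term_id))
    return results


def rank_and_flag(
    results: list[EnrichmentResult], cutoffs: LevelCutoffs
) -> list[EnrichmentResult]:
    """Assign per-level competition ranks and significance flags.

    Within each level, ties on p share the smallest applicable rank (rank =
    number of strictly smaller p-values + 1); a result is significant iff
    p <= max_p and rank <= max_rank for its level.  Input must come from a
    single dataset.  Returns new result objects, sorted.
    """
    if len({r.dataset_name for r in results}) > 1:
        raise ParameterError("rank_and_flag expects results from a single dataset")
    out: list[EnrichmentResult] = []
    by_level: dict[Optional[int], list[EnrichmentResult]] = {}
    for r in results:
        by_level.setdefault(r.level, []).append(r)
    for level, group in by_level.items():
        max_p, max_rank = cutoffs.for_level(level)
        pvals = sorted(r.p_value for r in group)
        for r in sorted(group, key=lambda r: (r.p_value, r.term_id)):
            rank = 1 + _count_strictly_less(pvals, r.p_value)
            out.append(
                replace(
                    r,
                    rank=rank,
                    significant=(r.p_value <= max_p and rank <= max_rank),
                    overlap_genes=set(r.overlap_genes),
                    contributing_merged_ids=set(r.contributing_merged_ids),
                )
            )
    out.sort(key=lambda r: (_level_sort_key(r.level), r.p_value, r.term_id))
    return out


def _count_strictly_less(sorted_vals: list[float], x: float) -> int:
    import bisect

    return bisect.bisect_left(sorted_vals, x)


# ---------------------------------------------------------------------------
# dynamic analysis
# ---------------------------------------------------------------------------

def enumerate_merged_scps(
    analyzed: set[str],
    ontology: Ontology,
    network: InteractionNetwork,
    percent: float,
    level: Optional[int],
) -> list[MergedSCP]:
    """Enumerate dataset-selective merged SCPs at one level.

    Candidates are same-level terms containing at least one analyzed gene.
    Every 2- or 3-subset of candidates whose induced subgraph in the
    top-``percent`` interaction network (restricted to same-level edges) is
    connected yields a merged SCP whose gene set is the members' union.
    """
    level_ids = {t.term_id for t in ontology.terms_at_level(level)}
    sub = network.subgraph(level_ids)
    if not len(sub):
        return []
    top = top_percent_interactions(sub, percent)
    candidates = sorted(
        tid for tid in level_ids if ontology.terms[tid].genes & analyzed
    )
    cand_set = set(candidates)
    merged: list[MergedSCP] = []

    def make(members: tuple[str, ...]) -> MergedSCP:
        genes: set[str] = set()
        for m in members:
            genes |= ontology.terms[m].genes
        return MergedSCP(
            merged_id=merged_scp_id(members),
            member_ids=members,
            genes=frozenset(genes),
            level=level,
        )

    for (a, b) in sorted(top.weights):
        if a in cand_set and b in cand_set:
            merged.append(make(tuple(sorted((a, b)))))
    for trio in combinations(candidates, 3):
        n_edges = sum(
            top.has_edge(x, y) for x, y in combinations(trio, 2)
        )
        if n_edges >= 2:  # any two edges connect three nodes
            merged.append(make(trio))
    merged.sort(key=lambda m: m.merged_id)
    return merged


def dynamic_combined_results(
    dataset: Dataset,
    ontology: Ontology,
    network: InteractionNetwork,
    percent: float,
    cutoffs: LevelCutoffs,
) -> list[EnrichmentResult]:
    """The combined (singleton + merged) dynamic ranking, before splitting.

    Per level, the dataset-selective term collection is the original
    same-level terms plus the enumerated merged SCPs; all are Fisher-tested
    against the same universe and ranked together under the dynamic
    cutoffs.  Merged-term results carry their member composition in
    ``member_ids``.
    """
    universe, analyzed = build_universe(dataset, ontology)
    n = len(analyzed)
    N = len(universe)
    levels = ontology.levels() or [None]
    out: list[EnrichmentResult] = []
    for level in levels:
        combined: list[EnrichmentResult] = []
        for term in ontology.terms_at_level(level):
            term_genes = term.genes & universe
            overlap = term_genes & analyzed
            if not overlap:
                continue
            counts = ContingencyCounts(k=len(overlap), n=n, K=len(term_genes), N=N)
            p = fisher_right_tail(counts)
            combined.append(
                EnrichmentResult(
                    dataset_name=dataset.name,
                    term_id=term.term_id,
                    term_name=term.name,
                    counts=counts,
                    p_value=p,
                    minus_log10_p=_log10_p(p),
                    overlap_genes=overlap,
                    level=level,
                    source="dynamic",
                )
            )
        for m in enumerate_merged_scps(analyzed, ontology, network, percent, level):
            m_genes = set(m.genes) & universe
            overlap = m_genes & analyzed
            counts = ContingencyCounts(k=len(overlap), n=n, K=len(m_genes), N=N)
            p = fisher_right_tail(counts)
            combined.append(
                EnrichmentResult(
                    dataset_name=dataset.name,
                    term_id=m.merged_id,
                    term_name=" + ".join(
                        ontology.terms[x].name or x for x in m.member_ids
                    ),
                    counts=counts,
                    p_value=p,
                    minus_log10_p=_log10_p(p),
                    overlap_genes=overlap,
                    level=level,
                    source="dynamic",
                    member_ids=m.member_ids,
                )
            )
        out.extend(rank_and_flag(combined, cutoffs))
    return out


def dynamic_enrichment(
    dataset: Dataset,
    ontology: Ontology,
    network: InteractionNetwork,
    percent: float,
    cutoffs: LevelCutoffs,
) -> list[EnrichmentResult]:
    """Dynamic enrichment: test merged SCPs alongside the originals.

    Runs :func:`dynamic_combined_results` and converts the combined ranking
    into per-SCP results via :func:`split_dynamic`.  With no surviving
    interaction edges this reduces to standard enrichment.
    """
    combined = dynamic_combined_results(
        dataset, ontology, network, percent, cutoffs
    )
    out = split_dynamic(combined)
    out.sort(key=lambda r: (_level_sort_key(r.level), -r.minus_log10_p, r.term_id))
    return out


def split_dynamic(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Convert combined (singleton + merged) dynamic results to per-SCP results.

    Each *significant* merged result of m members contributes
    -log10(p)/m to every member; a singleton's own full -log10(p) counts
    when the singleton itself is significant.  Per SCP the contributions
    are summed and the contributing merged ids recorded.  Counts, p-value,
    rank and significance flag of the per-SCP result stay those of the
    SCP's own singleton test.
    """
    singles = {r.term_id: r for r in results if not r.member_ids}
    contributions: dict[str, list[float]] = {tid: [] for tid in singles}
    merged_of: dict[str, set[str]] = {tid: set() for tid in singles}
    for r in results:
        if not r.member_ids:
            if r.significant:
                contributions[r.term_id].append(r.minus_log10_p)
        elif r.significant:
            share = r.minus_log10_p / len(r.member_ids)
            for m in r.member_ids:
                # members always have a singleton test: each contains >= 1
                # analyzed gene, so k >= 1
                contributions[m].append(share)
                merged_of[m].add(r.term_id)
    out = []
    for tid, r in singles.items():
        out.append(
            replace(
                r,
                minus_log10_p=math.fsum(contributions[tid]),
                contributing_merged_ids=merged_of[tid],
                overlap_genes=set(r.overlap_genes),
            )
        )
    return out


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "dataset", "integration_group", "ontology", "level", "term_id",
    "term_name", "k", "n", "K", "N", "p_value", "minus_log10_p", "rank",
    "significant", "source", "overlap_genes", "contributing_merged_ids",
    "p_bh",
]


def results_to_table(
    results: list[EnrichmentResult],
    dataset: Optional[Dataset] = None,
    ontology_name: str = "",
) -> pd.DataFrame:
    """Flatten results into the tabular output schema.

    ``p_bh`` (Benjamini-Hochberg adjusted p, per dataset) is supplementary
    and plays no role in significance.
    """
    rows = []
    for r in results:
        rows.append({
            "dataset": r.dataset_name,
            "integration_group": dataset.integration_group if dataset else "",
            "ontology": ontology_name,
            "level": r.level,
            "term_id": r.term_id,
            "term_name": r.term_name,
            "k": r.counts.k,
            "n": r.counts.n,
            "K": r.counts.K,
            "N": r.counts.N,
            "p_value": r.p_value,
            "minus_log10_p": r.minus_log10_p,
            "rank": r.rank,
            "significant": r.significant,
            "source": r.source,
            "overlap_genes": ";".join(sorted(r.overlap_genes)),
            "contributing_merged_ids": ";".join(sorted(r.contributing_merged_ids)),
        })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if len(df):
        df["p_bh"] = false_discovery_control(df["p_value"].to_numpy(), method="bh")
    else:
        df["p_bh"] = pd.Series(dtype=float)
    return df
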