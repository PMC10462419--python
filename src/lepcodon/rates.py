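"""Category-aware substitution counting on a fixed species tree.

Substitutions are partitioned into six cells: {synonymous, nonsynonymous}
× {S→W (GC-decreasing), W→S (GC-increasing), GC-conservative}.  Ancestral
codon states are reconstructed by Fitch parsimony on the fixed topology;
parent→child codon changes are decomposed into single-base steps averaged
over all stop-free orderings (the Nei–Gojobori pathway convention), and
counts are normalized per cell by fractional mutational-opportunity site
counts computed from the parent state (each of a codon's nine single-base
neighbors contributes 1/3 site to its cell; changes into stop codons are
excluded from both counts and opportunities).

This is a deliberate counting approximation to probabilistic substitution
mapping under a codon model: it is exact for small divergences, fully
deterministic given a seed for parsimony tie-breaks, and testable against
enumeration oracles.  Absolute rate scales are not comparable with
model-based mappers; relative and ordinal patterns are.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import dendropy
import numpy as np

from .genetics import (
    GeneticCode,
    is_unambiguous_codon,
    single_step_class,
    standard_code,
)
from .qc import CodonAlignment

#: Cell order used by every 6-vector in this module.
CELLS: tuple[tuple[str, str], ...] = (
    ("syn", "SW"),
    ("syn", "WS"),
    ("syn", "conservative"),
    ("nonsyn", "SW"),
    ("nonsyn", "WS"),
    ("nonsyn", "conservative"),
)
CELL_INDEX = {cell: i for i, cell in enumerate(CELLS)}
SYN_SLICE = slice(0, 3)
NONSYN_SLICE = slice(3, 6)


@lru_cache(maxsize=None)
def codon_path_classification(codon_from: str, codon_to: str) -> tuple[float, ...] | None:
    """Average per-cell step counts over stop-free single-base paths.

    For codons differing at k positions, all k! orderings of the single
    base changes are enumerated; orderings passing through a stop codon
    are discarded and the per-step classifications of the remainder are
    averaged with equal weights.  Returns a 6-tuple in :data:`CELLS`
    order, or None when every ordering is forced through a stop.
    """
    code = standard_code()
    a, b = codon_from.upper(), codon_to.upper()
    if not (code.is_sense(a) and code.is_sense(b)):
        raise ValueError(f"{a}->{b}: both codons must be sense codons")
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return tuple(0.0 for _ in CELLS)
    acc = np.zeros(len(CELLS))
    n_valid = 0
    for order in itertools.permutations(diffs):
        current = a
        steps = []
        ok = True
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            if code.is_stop(nxt):
                ok = False
                break
            steps.append(single_step_class(current, nxt, code))
            current = nxt
        if not ok:
            continue
        n_valid += 1
        for cell in steps:
            acc[CELL_INDEX[cell]] += 1
    if n_valid == 0:
        return None
    return tuple(acc / n_valid)


@lru_cache(maxsize=None)
def site_opportunities(codon: str) -> tuple[float, ...]:
    """Fractional mutational-opportunity sites per cell for one sense codon.

    Each of the nine single-base neighbors contributes 1/3 of a site to
    its (effect × direction) cell; neighbors that are stop codons are
    excluded entirely.
    """
    code = standard_code()
    c = codon.upper()
    if not code.is_sense(c):
        raise ValueError(f"{codon!r} is not a sense codon")
    opp = np.zeros(len(CELLS))
    from .genetics import all_single_neighbors

    for _, _, nb in all_single_neighbors(c):
        if code.is_stop(nb):
            continue
        opp[CELL_INDEX[single_step_class(c, nb, code)]] += 1 / 3
    return tuple(opp)


@dataclass
class SubstitutionTally:
    """Per-(gene, branch) substitution counts and opportunities.

    ``counts`` and ``opportunities`` are 6-vectors in :data:`CELLS` order.
    """

    gene_id: str
    branch_id: str
    counts: np.ndarray = field(default_factory=lambda: np.zeros(len(CELLS)))
    opportunities: np.ndarray = field(default_factory=lambda: np.zeros(len(CELLS)))

    def add(self, other: "SubstitutionTally") -> "SubstitutionTally":
        self.counts = self.counts + other.counts
        self.opportunities = self.opportunities + other.opportunities
        return self

    def rate(self, effect: str, direction: str) -> float:
        i = CELL_INDEX[(effect, direction)]
        L = self.opportunities[i]
        return self.counts[i] / L if L > 0 else np.nan

    @property
    def dn(self) -> float:
        L = self.opportunities[NONSYN_SLICE].sum()
        return self.counts[NONSYN_SLICE].sum() / L if L > 0 else np.nan

    @property
    def ds(self) -> float:
        L = self.opportunities[SYN_SLICE].sum()
        return self.counts[SYN_SLICE].sum() / L if L > 0 else np.nan

    @property
    def omega(self) -> float:
        ds = self.ds
        if not np.isfinite(ds) or ds == 0:
            return np.nan
        return self.dn / ds

    def omega_category(self, direction: str) -> float:
        ds = self.rate("syn", direction)
        if not np.isfinite(ds) or ds == 0:
            return np.nan
        return self.rate("nonsyn", direction) / ds


def load_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted newick topology; internal nodes get stable ids."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    counter = 0
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            node.node_id = node.taxon.label
        else:
            node.node_id = f"node{counter}"
            counter += 1
    return tree


def _column_codons(aln: CodonAlignment, j: int, code: GeneticCode) -> dict[str, str] | None:
    """Sense codon per lineage at column j, or None if the column is masked."""
    col = aln.codon_column(j)
    for codon in col.values():
        if not is_unambiguous_codon(codon) or not code.is_sense(codon):
            return None
    return col


def ancestral_states(
    tree: dendropy.Tree,
    aln: CodonAlignment,
    seed: int = 0,
    strict: bool = False,
    code: GeneticCode | None = None,
) -> tuple[dict[str, list[str | None]], list[bool]]:
    """Fitch-parsimony codon states for every node and codon column.

    Columns containing a gap, ambiguous or stop codon in any leaf are
    masked (the tally simply skips them).  Ambiguity in the most-
    parsimonious assignment is resolved by uniform random choice with the
    given ``seed``; in ``strict`` mode ambiguous columns are masked
    instead.

    Returns ``(states, included)``: states maps node_id → list of codons
    (None at masked columns), included flags columns that entered the
    reconstruction.
    """
    code = code or standard_code()
    rng = np.random.default_rng(seed)
    nodes = list(tree.preorder_node_iter())
    states: dict[str, list[str | None]] = {n.node_id: [None] * aln.n_codons for n in nodes}
    included = [False] * aln.n_codons

    for j in range(aln.n_codons):
        col = _column_codons(aln, j, code)
        if col is None:
            continue
        # Fitch up-pass on codon state sets.
        sets: dict[str, frozenset[str]] = {}
        ambiguous = False
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                sets[node.node_id] = frozenset([col[node.taxon.label]])
            else:
                child_sets = [sets[ch.node_id] for ch in node.child_nodes()]
                inter = frozenset.intersection(*child_sets)
                sets[node.node_id] = inter if inter else frozenset.union(*child_sets)
        # Down-pass assignment.
        assign: dict[str, str] = {}
        for node in tree.preorder_node_iter():
            s = sets[node.node_id]
            if node.parent_node is None:
                if len(s) == 1:
                    assign[node.node_id] = next(iter(s))
                else:
                    ambiguous = True
                    assign[node.node_id] = sorted(s)[rng.integers(len(s))]
            else:
                parent_state = assign[node.parent_node.node_id]
                if parent_state in s:
                    assign[node.node_id] = parent_state
                elif len(s) == 1:
                    assign[node.node_id] = next(iter(s))
                else:
                    ambiguous = True
                    assign[node.node_id] = sorted(s)[rng.integers(len(s))]
        if strict and ambiguous:
            continue
        included[j] = True
        for nid, codon in assign.items():
            states[nid][j] = codon
    return states, included


def branch_rates(
    tree: dendropy.Tree,
    aln: CodonAlignment,
    seed: int = 0,
    strict: bool = False,
    code: GeneticCode | None = None,
) -> dict[str, SubstitutionTally]:
    """Per-branch category tallies for one gene on a fixed topology.

    A branch is identified by its child node id.  Opportunities accumulate
    from the parent state of every included column; parent→child changes
    contribute pathway-averaged counts.  Codon pairs whose every pathway
    crosses a stop codon are skipped entirely (counts and opportunities).
    """
    code = code or standard_code()
    states, included = ancestral_states(tree, aln, seed=seed, strict=strict, code=code)
    tallies: dict[str, SubstitutionTally] = {}
    edges = [
        (n.parent_node.node_id, n.node_id)
        for n in tree.preorder_node_iter()
        if n.parent_node is not None
    ]
    for parent_id, child_id in edges:
        tal = SubstitutionTally(aln.gene_id, child_id)
        for j, ok in enumerate(included):
            if not ok:
                continue
            p = states[parent_id][j]
            c = states[child_id][j]
            if p == c:
                tal.opportunities += np.asarray(site_opportunities(p))
                continue
            path = codon_path_classification(p, c)
            if path is None:
                continue
            tal.opportunities += np.asarray(site_opportunities(p))
            tal.counts += np.asarray(path)
        tallies[child_id] = tal
    return tallies


def pairwise_rates(parent_seq: str, child_seq: str, gene_id: str = "", code: GeneticCode | None = None) -> SubstitutionTally:
    """Direct parent→child tally for an aligned ungapped sequence pair.

    Used when the ancestral sequence is known (simulations) and as the
    2-taxon special case of :func:`branch_rates`.
    """
    code = code or standard_code()
    if len(parent_seq) != len(child_seq):
        raise ValueError("sequences must be aligned to equal length")
    tal = SubstitutionTally(gene_id, "pair")
    for i in range(0, len(parent_seq), 3):
        p, c = parent_seq[i:i + 3].upper(), child_seq[i:i + 3].upper()
        if not (is_unambiguous_codon(p) and is_unambiguous_codon(c)):
            continue
        if not (code.is_sense(p) and code.is_sense(c)):
            continue
        if p == c:
            tal.opportunities += np.asarray(site_opportunities(p))
            continue
        path = codon_path_classification(p, c)
        if path is None:
            continue
        tal.opportunities += np.asarray(site_opportunities(p))
        tal.counts += np.asarray(path)
    return tal


def aggregate_tallies(tallies, branch_id: str = "all", gene_id: str = "all") -> SubstitutionTally:
    """Sum counts and opportunities across tallies (e.g. genes of one branch)."""
    out = SubstitutionTally(gene_id, branch_id)
    for t in tallies:
        out.add(t)
    return out


def sw_ratio(tallies, effect: str = "syn") -> dict:
    """S→W / W→S rate ratios across tallies with summary statistics.

    Tallies with a zero or undefined denominator rate are excluded from
    the summaries and counted in ``n_excluded``.
    """
    ratios = []
    excluded = 0
    for t in tallies:
        d_sw = t.rate(effect, "SW")
        d_ws = t.rate(effect, "WS")
        if not np.isfinite(d_sw) or not np.isfinite(d_ws) or d_ws == 0:
            excluded += 1
            continue
        ratios.append(d_sw / d_ws)
    arr = np.asarray(ratios)
    return {
        "ratios": arr,
        "n": len(arr),
        "n_excluded": excluded,
        "mean": float(arr.mean()) if len(arr) else np.nan,
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else np.nan,
        "median": float(np.median(arr)) if len(arr) else np.nan,
    }
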