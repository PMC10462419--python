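"""Genetic-code tables, strong/weak base classes, site degeneracy and GC metrics.

Everything downstream — codon-usage statistics, substitution-category
counting, and the population-genetic site classification — shares these
primitives.  Bases are classified as strong (S = G/C, three hydrogen bonds)
or weak (W = A/T, two hydrogen bonds); substitutions and mutations are
later binned as S→W (GC-decreasing), W→S (GC-increasing) or
GC-conservative (S→S and W→W pooled).

The standard nuclear genetic code is the default; a different code table
can be injected wherever a ``GeneticCode`` is accepted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable

BASES = ("A", "C", "G", "T")
STRONG = frozenset("GC")
WEAK = frozenset("AT")
GAP_CHARS = frozenset("-.")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class UnclassifiableBaseError(ValueError):
    """Raised when a base outside {A,C,G,T} is asked for an S/W class."""


def classify_base(base: str) -> str:
    """Return ``"S"`` for G/C and ``"W"`` for A/T.

    Ambiguity codes (N, R, Y, ...) and gaps raise
    :class:`UnclassifiableBaseError`; the caller decides whether to mask.
    """
    b = base.upper()
    if b in STRONG:
        return "S"
    if b in WEAK:
        return "W"
    raise UnclassifiableBaseError(f"cannot assign S/W class to base {base!r}")


def mutation_class(anc: str, der: str) -> str:
    """Classify a base change as ``"SW"``, ``"WS"`` or ``"conservative"``."""
    a, d = classify_base(anc), classify_base(der)
    if a == d:
        return "conservative"
    return "SW" if a == "S" else "WS"


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in {seq!r}") from exc


class GeneticCode:
    """A codon → amino-acid map with per-position degeneracy classes.

    Parameters
    ----------
    table_id:
        NCBI translation-table id (1 = standard nuclear code, the default).
    """

    def __init__(self, table_id: int = 1):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.forward = {c.upper(): aa for c, aa in table.forward_table.items()}
        self.stop_codons = frozenset(c.upper() for c in table.stop_codons)
        self.sense_codons = tuple(sorted(self.forward))
        if table_id == 1 and len(self.sense_codons) != 61:
            raise AssertionError("standard code must have 61 sense codons")
        # amino acid -> synonymous family (sorted tuple of codons)
        fams: dict[str, list[str]] = {}
        for codon, aa in self.forward.items():
            fams.setdefault(aa, []).append(codon)
        self.families = {aa: tuple(sorted(cs)) for aa, cs in fams.items()}
        self.amino_acids = tuple(sorted(self.families))

    def translate(self, codon: str) -> str | None:
        """Amino acid for a sense codon, ``"*"`` for a stop, None otherwise."""
        c = codon.upper()
        if c in self.forward:
            return self.forward[c]
        if c in self.stop_codons:
            return "*"
        return None

    def is_sense(self, codon: str) -> bool:
        return codon.upper() in self.forward

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def family_size(self, aa: str) -> int:
        return len(self.families[aa])

    def site_degeneracy(self, codon: str, position: int) -> int:
        """Degeneracy fold-class of one codon position.

        Returns the number of nucleotides at ``position`` (1-based, 1..3)
        that, holding the other two positions fixed, encode the same amino
        acid — except that 1 is reported as 0 ("0-fold": no synonymous
        alternative).  Stop codons raise ``ValueError``.
        """
        c = codon.upper()
        if position not in (1, 2, 3):
            raise ValueError(f"codon position must be 1..3, got {position}")
        if c not in self.forward:
            raise ValueError(f"{codon!r} is not a sense codon")
        aa = self.forward[c]
        idx = position - 1
        count = sum(
            1
            for b in BASES
            if self.forward.get(c[:idx] + b + c[idx + 1:]) == aa
        )
        return 0 if count == 1 else count


@lru_cache(maxsize=4)
def standard_code(table_id: int = 1) -> GeneticCode:
    return GeneticCode(table_id)


def is_gap_codon(codon: str) -> bool:
    return any(ch in GAP_CHARS for ch in codon)


def is_unambiguous_codon(codon: str) -> bool:
    return all(ch in "ACGT" for ch in codon.upper())


def iter_codons(seq: str):
    """Yield successive triplets of an in-frame sequence.

    Raises ``ValueError`` if the length is not divisible by 3.
    """
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    for i in range(0, len(seq), 3):
        yield seq[i:i + 3]


@dataclass(frozen=True)
class GCProfile:
    """Codon-position-specific GC fractions of one in-frame sequence.

    ``gc12`` is the mean of the first- and second-position fractions; it is
    used as a proxy for regional composition under selective constraint,
    whereas ``gc3`` is dominated by synonymous sites.  ``n_codons`` counts
    the gap-free, unambiguous codons actually included.  ``valid`` is False
    when nothing was countable.
    """

    gene_id: str | None
    lineage_id: str | None
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    n_codons: int
    valid: bool = True


def gc_by_position(
    seq: str,
    gene_id: str | None = None,
    lineage_id: str | None = None,
    code: GeneticCode | None = None,
) -> GCProfile:
    """Per-codon-position GC fractions over gap-free unambiguous codons.

    Stop codons are skipped (they are not part of the codon-usage universe).
    An empty result after masking is returned flagged ``valid=False`` so the
    caller can exclude it downstream instead of crashing.
    """
    code = code or standard_code()
    gc = [0, 0, 0]
    n = 0
    for codon in iter_codons(seq.upper()):
        if not is_unambiguous_codon(codon) or code.is_stop(codon):
            continue
        n += 1
        for i, b in enumerate(codon):
            if b in STRONG:
                gc[i] += 1
    if n == 0:
        return GCProfile(gene_id, lineage_id, 0.0, 0.0, 0.0, 0.0, 0, valid=False)
    g1, g2, g3 = (g / n for g in gc)
    return GCProfile(gene_id, lineage_id, g1, g2, g3, (g1 + g2) / 2, n)


def single_step_class(codon_from: str, codon_to: str, code: GeneticCode | None = None) -> tuple[str, str]:
    """Classify a one-base codon change as (effect, direction).

    effect ∈ {"syn", "nonsyn"}; direction ∈ {"SW", "WS", "conservative"}.
    Both codons must be sense codons differing at exactly one position.
    """
    code = code or standard_code()
    a, b = codon_from.upper(), codon_to.upper()
    diffs = [i for i in range(3) if a[i] != b[i]]
    if len(diffs) != 1:
        raise ValueError(f"{a}->{b} is not a single-base change")
    if not (code.is_sense(a) and code.is_sense(b)):
        raise ValueError(f"{a}->{b} involves a non-sense codon")
    i = diffs[0]
    effect = "syn" if code.forward[a] == code.forward[b] else "nonsyn"
    return effect, mutation_class(a[i], b[i])


def all_single_neighbors(codon: str):
    """All (position_index, alt_base, neighbor_codon) single-base variants."""
    c = codon.upper()
    for i, alt in itertools.product(range(3), BASES):
        if alt != c[i]:
            yield i, alt, c[:i] + alt + c[i + 1:]
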