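"""Codon usage tables, RSCU, and the effective number of codons (ENC).

RSCU (relative synonymous codon usage) compares a codon's frequency with
the equal-usage expectation within its synonymous family: RSCU = 1 means
no preference, >1 overrepresentation.

ENC_obs is Wright's effective number of codons, computed from family
"homozygosities" F = (n·Σp_i² − 1)/(n − 1) and ranging from 20 (one codon
per amino acid) to 61 (uniform usage).  ENC_exp is the value expected from
third-position base composition alone,

    ENC_exp = a + GC3 + b / (GC3² + (c − GC3)²),

with default constants a=6, b=34, c=1.025 (simulation-optimized for the
lepidopteran composition range; Wright's classic curve a=2, b=29, c=1 is
available through :class:`ENCConfig`).  Both ENC values are clamped to
[20, 61].  The normalized difference ENC_diff = (ENC_exp − ENC_obs)/ENC_exp
is the codon-usage-bias score: positive values mean stronger bias than
composition alone would produce.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .genetics import GeneticCode, gc_by_position, iter_codons, is_unambiguous_codon, standard_code

ENC_MIN, ENC_MAX = 20.0, 61.0


@dataclass(frozen=True)
class ENCConfig:
    """Constants of the composition-expected ENC curve."""

    a: float = 6.0
    b: float = 34.0
    c: float = 1.025

    @classmethod
    def wright_classic(cls) -> "ENCConfig":
        return cls(a=2.0, b=29.0, c=1.0)


@dataclass
class CodonUsageTable:
    """Sense-codon counts with per-1000 frequencies and RSCU values.

    ``scope`` names what was counted (a gene id, a lineage, ...).  RSCU is
    NaN for codons in families with zero total usage (undefined) and for
    the single-codon families (Met, Trp), where it is identically 1 but
    carries no information; those are reported as 1.0.
    """

    scope: str
    counts: dict[str, int]
    total: int
    per_1000: dict[str, float] = field(default_factory=dict)
    rscu_values: dict[str, float] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.total == 0


def codon_counts(sequences, code: GeneticCode | None = None) -> Counter:
    """Tally sense codons over one or more in-frame sequences.

    Gap-containing, ambiguous, and stop codons are skipped.
    """
    code = code or standard_code()
    if isinstance(sequences, str):
        sequences = [sequences]
    counts: Counter = Counter()
    for seq in sequences:
        for codon in iter_codons(seq.upper()):
            if is_unambiguous_codon(codon) and code.is_sense(codon):
                counts[codon] += 1
    return counts


def codon_frequencies(sequences, scope: str = "", code: GeneticCode | None = None) -> CodonUsageTable:
    """Build a :class:`CodonUsageTable` (counts, per-1000, RSCU) for sequences."""
    code = code or standard_code()
    counts = codon_counts(sequences, code)
    total = sum(counts.values())
    full = {c: counts.get(c, 0) for c in code.sense_codons}
    table = CodonUsageTable(scope=scope, counts=full, total=total)
    if total:
        table.per_1000 = {c: 1000.0 * n / total for c, n in full.items()}
        table.rscu_values = rscu(table, code)
    return table


def rscu(table: CodonUsageTable, code: GeneticCode | None = None) -> dict[str, float]:
    """RSCU per codon: family size × count / family total.

    Families with zero total usage get NaN (undefined, flagged rather than
    erroring).
    """
    code = code or standard_code()
    out: dict[str, float] = {}
    for aa, family in code.families.items():
        fam_total = sum(table.counts.get(c, 0) for c in family)
        k = len(family)
        for c in family:
            out[c] = (k * table.counts.get(c, 0) / fam_total) if fam_total else math.nan
    return out


def overrepresented_by_third_base(table: CodonUsageTable, code: GeneticCode | None = None) -> dict[str, int]:
    """Count overrepresented codons (RSCU > 1) ending in S (G/C) vs W (A/T)."""
    code = code or standard_code()
    rs = table.rscu_values or rscu(table, code)
    out = {"S": 0, "W": 0}
    for codon, val in rs.items():
        if code.family_size(code.forward[codon]) >= 2 and not math.isnan(val) and val > 1:
            out["S" if codon[2] in "GC" else "W"] += 1
    return out


def _family_homozygosity(counts: list[int]) -> float | None:
    """Wright's F̂ = (n·Σp² − 1)/(n − 1) for one synonymous family; None if n < 2."""
    n = sum(counts)
    if n < 2:
        return None
    s = sum((c / n) ** 2 for c in counts)
    return (n * s - 1) / (n - 1)


def enc_obs(table: CodonUsageTable, code: GeneticCode | None = None) -> float | None:
    """Wright's observed effective number of codons, clamped to [20, 61].

    F values are averaged within degeneracy classes (2-, 3-, 4-, 6-synonym
    families) and combined as ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆.
    Following Wright's conventions for short genes, a missing F̄₃ (Ile not
    observed twice) is imputed as the mean of F̄₂ and F̄₄, and any other
    missing class as the mean of the estimated classes.  Returns None when
    no family at all is estimable, and None when an averaged F̄ is 0
    (a class observed but maximally heterogeneous at n=2 cannot happen;
    F=0 can, for counts like (1,1), making 1/F̄ blow up — such genes are
    reported as None and excluded upstream).
    """
    code = code or standard_code()
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    n_single = 0
    for aa, family in code.families.items():
        k = len(family)
        if k == 1:
            n_single += 1
            continue
        f = _family_homozygosity([table.counts.get(c, 0) for c in family])
        if f is not None:
            by_class[k].append(f)

    fbar: dict[int, float] = {
        k: sum(v) / len(v) for k, v in by_class.items() if v
    }
    if not fbar:
        return None
    if 3 not in fbar:
        if 2 in fbar and 4 in fbar:
            fbar[3] = (fbar[2] + fbar[4]) / 2
        else:
            fbar[3] = sum(fbar.values()) / len(fbar)
    for k in (2, 4, 6):
        if k not in fbar:
            fbar[k] = sum(fbar.values()) / len(fbar)
    if min(fbar.values()) <= 0:
        return None
    enc = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(ENC_MAX, max(ENC_MIN, enc))


def enc_exp(gc3: float, config: ENCConfig | None = None) -> float:
    """Composition-expected ENC at a given third-position GC fraction.

    Clamped to [20, 61]; GC3 outside [0, 1] is an error.
    """
    if not 0.0 <= gc3 <= 1.0:
        raise ValueError(f"GC3 must lie in [0,1], got {gc3}")
    cfg = config or ENCConfig()
    val = cfg.a + gc3 + cfg.b / (gc3 ** 2 + (cfg.c - gc3) ** 2)
    return min(ENC_MAX, max(ENC_MIN, val))


def enc_diff(expected: float, observed: float) -> float:
    """Normalized ENC difference (exp − obs)/exp: the codon-usage-bias score."""
    if expected <= 0:
        raise ValueError("ENC_exp must be positive")
    return (expected - observed) / expected


@dataclass(frozen=True)
class ENCRecord:
    """Per gene × lineage ENC summary row."""

    gene_id: str
    lineage_id: str
    gc3: float
    enc_observed: float
    enc_expected: float
    enc_difference: float


def enc_record(
    gene_id: str,
    lineage_id: str,
    sequence: str,
    config: ENCConfig | None = None,
    code: GeneticCode | None = None,
) -> ENCRecord | None:
    """GC3, ENC_obs, ENC_exp and ENC_diff for one ungapped gene sequence.

    Returns None when the gene is too short/degenerate for ENC_obs or has
    no countable codons.
    """
    code = code or standard_code()
    profile = gc_by_position(sequence, gene_id, lineage_id, code)
    if not profile.valid:
        return None
    table = codon_frequencies(sequence, scope=gene_id, code=code)
    obs = enc_obs(table, code)
    if obs is None:
        return None
    exp = enc_exp(profile.gc3, config)
    return ENCRecord(gene_id, lineage_id, profile.gc3, obs, exp, enc_diff(exp, obs))


def pooled_usage(tables: list[CodonUsageTable], scope: str, code: GeneticCode | None = None) -> CodonUsageTable:
    """Lineage-level usage from pooled counts (not means of per-gene frequencies)."""
    code = code or standard_code()
    pooled: Counter = Counter()
    for t in tables:
        pooled.update(t.counts)
    total = sum(pooled.values())
    full = {c: pooled.get(c, 0) for c in code.sense_codons}
    out = CodonUsageTable(scope=scope, counts=full, total=total)
    if total:
        out.per_1000 = {c: 1000.0 * n / total for c, n in full.items()}
        out.rscu_values = rscu(out, code)
    return out
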