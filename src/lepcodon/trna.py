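"""tRNA gene-prediction parsing and isoacceptor copy-number statistics.

Reads the tRNAscan-SE 2.x tabular output, removes pseudogenes and
truncated gene models, and summarizes the functional repertoire:
per-anticodon and per-amino-acid (isoacceptor family) copy numbers, the
relative abundance of isoacceptor tRNAs (RAIT — the copy-number analogue
of RSCU, computed with family size = number of synonymous codons), and
the GC-content at third codon positions of the codon equivalents
(anticodon reverse complements), copy-weighted by default.

Wobble pairing is deliberately not modeled: each anticodon maps to its
single Watson–Crick codon equivalent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from statistics import median

from .genetics import GeneticCode, reverse_complement, standard_code


@dataclass(frozen=True)
class TRNAGene:
    """One tRNA gene model from a tRNAscan-SE table."""

    chrom: str
    begin: int
    end: int
    strand: str
    isotype: str          # amino-acid three-letter name as printed (e.g. "Gly")
    anticodon: str        # 5'->3'
    score: float
    pseudo: bool
    truncated: bool

    @property
    def functional(self) -> bool:
        return not (self.pseudo or self.truncated)


def parse_trnascan(path) -> tuple[list[TRNAGene], int]:
    """Parse a tRNAscan-SE 2.x tabular file.

    Handles the three header lines, minus-strand rows (begin > end in the
    source; normalized here with strand inferred) and "pseudo"/"trunc"
    annotations in the Note column or Isotype field.  Malformed rows are
    skipped; the skipped-row count is returned alongside the records.
    """
    genes: list[TRNAGene] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(("Sequence", "Name", "--")):
                continue  # header block
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                skipped += 1
                continue
            try:
                chrom = cols[0].strip()
                begin, end = int(cols[2]), int(cols[3])
                isotype = cols[4].strip()
                anticodon = cols[5].strip().upper()
                score = float(cols[8])
            except (ValueError, IndexError):
                skipped += 1
                continue
            note = cols[9].lower() if len(cols) > 9 else ""
            strand = "+"
            if begin > end:
                begin, end = end, begin
                strand = "-"
            genes.append(
                TRNAGene(
                    chrom=chrom,
                    begin=begin,
                    end=end,
                    strand=strand,
                    isotype=isotype,
                    anticodon=anticodon,
                    score=score,
                    pseudo="pseudo" in note or isotype.lower() == "pseudo",
                    truncated="trunc" in note,
                )
            )
    return genes, skipped


def filter_functional(
    genes: list[TRNAGene],
    chromosome_allowlist: set[str] | None = None,
) -> list[TRNAGene]:
    """Drop pseudogenes, truncated models and undetermined anticodons.

    ``chromosome_allowlist`` restricts to named sequences (e.g. the
    chromosome-level scaffolds of an assembly).
    """
    out = []
    for g in genes:
        if not g.functional:
            continue
        if set(g.anticodon) - set("ACGT"):
            continue
        if chromosome_allowlist is not None and g.chrom not in chromosome_allowlist:
            continue
        out.append(g)
    return out


def anticodon_to_codon(anticodon: str) -> str:
    """Watson–Crick codon equivalent: reverse complement read 5'→3'."""
    a = anticodon.upper()
    if len(a) != 3 or set(a) - set("ACGT"):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    return reverse_complement(a)


@dataclass
class TRNASummary:
    """Copy numbers, RAIT values and composition of a tRNA repertoire."""

    copies_per_anticodon: dict[str, int]
    copies_per_amino_acid: dict[str, int]
    rait_values: dict[str, float] = field(default_factory=dict)

    @property
    def total_genes(self) -> int:
        return sum(self.copies_per_anticodon.values())

    @property
    def unique_anticodons(self) -> int:
        return len(self.copies_per_anticodon)

    def copy_number_summary(self) -> dict:
        vals = sorted(self.copies_per_anticodon.values())
        if not vals:
            return {"median": None, "min": None, "max": None}
        return {"median": median(vals), "min": vals[0], "max": vals[-1]}

    def outliers(self, factor: float = 2.0) -> dict[str, int]:
        """Anticodons with copy number > factor × the rest's maximum."""
        items = sorted(self.copies_per_anticodon.items(), key=lambda kv: kv[1])
        if len(items) < 2:
            return {}
        top_ac, top_n = items[-1]
        rest_max = items[-2][1]
        return {top_ac: top_n} if top_n > factor * rest_max else {}


def copy_numbers(genes: list[TRNAGene], code: GeneticCode | None = None) -> TRNASummary:
    """Per-anticodon and per-amino-acid copy counts of a filtered gene list."""
    code = code or standard_code()
    per_ac = Counter(g.anticodon for g in genes)
    per_aa: Counter = Counter()
    for ac, k in per_ac.items():
        codon = anticodon_to_codon(ac)
        aa = code.translate(codon)
        if aa and aa != "*":
            per_aa[aa] += k
    summary = TRNASummary(dict(per_ac), dict(per_aa))
    summary.rait_values = rait(summary, code)
    return summary


def rait(summary: TRNASummary, code: GeneticCode | None = None) -> dict[str, float]:
    """Relative abundance of isoacceptor tRNAs per anticodon.

    RAIT(anticodon) = k × copies / family total, with k the number of
    synonymous codons of the amino acid — the expectation under equal use
    of all possible anticodons, mirroring RSCU.  Anticodons whose codon
    equivalent is a stop are skipped; absent families are simply not
    present in the output (undefined).
    """
    code = code or standard_code()
    by_aa: dict[str, dict[str, int]] = {}
    for ac, k in summary.copies_per_anticodon.items():
        aa = code.translate(anticodon_to_codon(ac))
        if aa and aa != "*":
            by_aa.setdefault(aa, {})[ac] = k
    out: dict[str, float] = {}
    for aa, acs in by_aa.items():
        fam_total = sum(acs.values())
        ksize = code.family_size(aa)
        for ac, copies in acs.items():
            out[ac] = ksize * copies / fam_total
    return out


def overrepresented_by_third_base(summary: TRNASummary, code: GeneticCode | None = None) -> dict[str, int]:
    """Count RAIT > 1 anticodons by their codon equivalent's third base class."""
    out = {"S": 0, "W": 0}
    for ac, val in summary.rait_values.items():
        if val > 1:
            codon = anticodon_to_codon(ac)
            out["S" if codon[2] in "GC" else "W"] += 1
    return out


def gc3_of_codon_equivalents(
    summary: TRNASummary,
    copy_weighted: bool = True,
    exclude_anticodons: set[str] | None = None,
) -> float:
    """GC fraction at third positions of the repertoire's codon equivalents.

    Copy-weighted by default; set ``copy_weighted=False`` for one vote per
    unique anticodon.  ``exclude_anticodons`` supports the outlier toggle.
    """
    exclude = exclude_anticodons or set()
    gc = tot = 0
    for ac, copies in summary.copies_per_anticodon.items():
        if ac in exclude:
            continue
        w = copies if copy_weighted else 1
        tot += w
        if anticodon_to_codon(ac)[2] in "GC":
            gc += w
    if tot == 0:
        raise ValueError("empty repertoire")
    return gc / tot
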