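"""Codon-alignment container and alignment hygiene filters.

The filters reproduce a standard comparative-genomics QC cascade for
codon-aware alignments of 1:1 orthologs:

* discard alignments with interspersed (non-terminal) stop codons or gap
  runs whose length is not a multiple of three (pseudogene / frameshift
  suspects);
* remove codon columns with a gap fraction strictly above 50% across
  lineages;
* discard alignments where any lineage has more than 50% missing codons,
  where the mean per-sequence gap fraction exceeds 25%, or that are shorter
  than 300 bp (100 codons) after trimming;
* after rate estimation, discard genes with dS > 30 (saturation) or
  ω ≥ 999 (no synonymous substitutions).

Thresholds are parameters with these values as defaults.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from Bio import SeqIO

from .genetics import GeneticCode, is_gap_codon, is_unambiguous_codon, standard_code

_GAP_RUN = re.compile(r"[-.]+")


@dataclass
class CodonAlignment:
    """An in-frame, possibly gapped multi-taxon codon alignment."""

    gene_id: str
    lineage_ids: list[str]
    sequences: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: sequences differ in length")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError(f"{self.gene_id}: alignment length not divisible by 3")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon_column(self, j: int) -> dict[str, str]:
        """Codon of every lineage at codon column ``j`` (0-based)."""
        return {lid: self.sequences[lid][3 * j:3 * j + 3] for lid in self.lineage_ids}

    @classmethod
    def from_fasta(cls, path, gene_id: str | None = None) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        seqs = {r.id: str(r.seq).upper() for r in records}
        return cls(gene_id or str(path), [r.id for r in records], seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for lid in self.lineage_ids:
                fh.write(f">{lid}\n{self.sequences[lid]}\n")


@dataclass
class FilterReport:
    """Per-gene record of which QC rules passed and why a gene was rejected."""

    gene_id: str
    rules: dict[str, bool] = field(default_factory=dict)  # rule -> passed
    values: dict[str, float] = field(default_factory=dict)
    columns_removed: int = 0

    @property
    def passed(self) -> bool:
        return all(self.rules.values())

    @property
    def failed_rules(self) -> list[str]:
        return [r for r, ok in self.rules.items() if not ok]


def check_frame_integrity(aln: CodonAlignment, code: GeneticCode | None = None) -> bool:
    """False if any sequence has an internal stop codon or an out-of-frame gap run.

    A stop codon in the final codon column is tolerated (terminal stop);
    interspersed stops and indels whose length is not a multiple of three
    mark putative pseudogenes / misannotations.
    """
    code = code or standard_code()
    last = aln.n_codons - 1
    for seq in aln.sequences.values():
        for run in _GAP_RUN.finditer(seq):
            if (run.end() - run.start()) % 3:
                return False
        for j in range(aln.n_codons):
            codon = seq[3 * j:3 * j + 3]
            if code.is_stop(codon) and j != last:
                return False
    return True


def trim_gap_columns(aln: CodonAlignment, max_gap_fraction: float = 0.5) -> tuple[CodonAlignment, int]:
    """Drop codon columns whose gap-codon fraction is strictly > ``max_gap_fraction``.

    A codon counts as a gap codon if it contains any gap character.  Whole
    codons are removed so frame is preserved.  Returns the trimmed alignment
    and the number of columns removed; an alignment trimmed to nothing is
    returned with length zero (the caller's length filter will reject it).
    """
    n_taxa = len(aln.lineage_ids)
    keep = []
    for j in range(aln.n_codons):
        gaps = sum(1 for c in aln.codon_column(j).values() if is_gap_codon(c))
        if gaps / n_taxa <= max_gap_fraction:
            keep.append(j)
    removed = aln.n_codons - len(keep)
    if removed == 0:
        return aln, 0
    seqs = {
        lid: "".join(aln.sequences[lid][3 * j:3 * j + 3] for j in keep)
        for lid in aln.lineage_ids
    }
    return CodonAlignment(aln.gene_id, list(aln.lineage_ids), seqs), removed


def _missing_codon_fraction(seq: str) -> float:
    n = len(seq) // 3
    if n == 0:
        return 1.0
    missing = sum(
        1
        for j in range(n)
        if is_gap_codon(seq[3 * j:3 * j + 3]) or not is_unambiguous_codon(seq[3 * j:3 * j + 3])
    )
    return missing / n


def filter_alignment(
    aln: CodonAlignment,
    min_length_bp: int = 300,
    max_missing_per_lineage: float = 0.5,
    max_mean_gap_fraction: float = 0.25,
    report: FilterReport | None = None,
) -> tuple[bool, FilterReport]:
    """Apply the post-trimming keep/reject rules to one alignment.

    Missing codons per lineage are counted at codon level (gap or ambiguous
    codons); the mean gap fraction is counted at nucleotide level.
    """
    rep = report or FilterReport(aln.gene_id)
    worst_missing = max(
        (_missing_codon_fraction(s) for s in aln.sequences.values()), default=1.0
    )
    gap_fracs = [
        sum(1 for ch in s if ch in "-.") / len(s) if s else 1.0
        for s in aln.sequences.values()
    ]
    mean_gap = sum(gap_fracs) / len(gap_fracs) if gap_fracs else 1.0

    rep.values["length_bp"] = aln.length
    rep.values["max_missing_fraction"] = worst_missing
    rep.values["mean_gap_fraction"] = mean_gap
    rep.rules["min_length"] = aln.length >= min_length_bp
    rep.rules["max_missing_per_lineage"] = worst_missing <= max_missing_per_lineage
    rep.rules["max_mean_gap"] = mean_gap <= max_mean_gap_fraction
    return rep.passed, rep


def filter_rate_outliers(
    ds: float | None,
    omega: float | None,
    max_ds: float = 30.0,
    max_omega: float = 999.0,
) -> tuple[bool, str]:
    """Keep/reject a gene on its gene-wide rate estimates.

    Rejects saturated genes (dS > 30) and genes without synonymous
    substitutions (ω ≥ 999); missing or non-finite rates are rejected as
    "unestimable".
    """
    if ds is None or omega is None or not (math.isfinite(ds) and math.isfinite(omega)):
        return False, "unestimable"
    if ds > max_ds:
        return False, "ds_saturated"
    if omega >= max_omega:
        return False, "omega_unbounded"
    return True, "ok"


def run_qc(
    alignments: list[CodonAlignment],
    code: GeneticCode | None = None,
    **filter_kwargs,
) -> tuple[list[CodonAlignment], list[FilterReport]]:
    """Full QC cascade: frame check, gap-column trimming, alignment filters.

    Returns the retained (trimmed) alignments and a report per input gene.
    Rate-outlier exclusion happens after rate estimation via
    :func:`filter_rate_outliers`, not here.
    """
    kept: list[CodonAlignment] = []
    reports: list[FilterReport] = []
    for aln in alignments:
        rep = FilterReport(aln.gene_id)
        rep.rules["frame_integrity"] = check_frame_integrity(aln, code)
        if not rep.rules["frame_integrity"]:
            reports.append(rep)
            continue
        trimmed, removed = trim_gap_columns(aln)
        rep.columns_removed = removed
        ok, rep = filter_alignment(trimmed, report=rep, **filter_kwargs)
        reports.append(rep)
        if ok:
            kept.append(trimmed)
    return kept, reports


def reports_to_rows(reports: list[FilterReport]) -> list[dict]:
    """Flatten reports for TSV export (gene, rule, value, decision)."""
    rows = []
    for rep in reports:
        for rule, ok in rep.rules.items():
            rows.append(
                {
                    "gene": rep.gene_id,
                    "rule": rule,
                    "value": rep.values.get(
                        {
                            "min_length": "length_bp",
                            "max_missing_per_lineage": "max_missing_fraction",
                            "max_mean_gap": "mean_gap_fraction",
                        }.get(rule, ""),
                        float("nan"),
                    ),
                    "decision": "pass" if ok else "fail",
                }
            )
    return rows
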