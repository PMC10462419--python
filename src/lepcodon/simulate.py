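"""Synthetic-data generators with full ground-truth bookkeeping.

Every input the pipeline consumes can be generated here with known truth:

* codon alignments evolved along a fixed 8-taxon tree by a per-site
  categorical substitution process honoring (syn/nonsyn × S→W/W→S/
  conservative) rate multipliers and avoiding stop codons;
* QC batches with planted filter violations (the generator's bookkeeping
  is the oracle for filter tests);
* polymorphism data drawn from the gBGC–mutation–drift equilibrium
  spectrum (Poisson per frequency bin) with known θ, B, λ and optional
  polarization error, emitted both as direct site tables and as
  VCF + reference FASTA + GFF3 + outgroup-TSV fixtures;
* tRNAscan-SE-style tables with planted copy numbers, pseudogene and
  minus-strand rows.

The polymorphism generator samples from the model's expected SFS rather
than running a coalescent: it tests estimator self-consistency, which is
what the recovery checks need.  Alignment simulation is site-independent
(no codon autocorrelation).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genetics import BASES, all_single_neighbors, classify_base, reverse_complement, single_step_class, standard_code
from .popgen import PolarizedSite, sfs_shape, _mix
from .qc import CodonAlignment
from .rates import CELLS, CELL_INDEX, load_tree

#: Balanced 8-taxon topology with butterfly-scale branch lengths
#: (substitutions per site).
DEFAULT_TREE = (
    "(((t1:0.06,t2:0.06):0.04,(t3:0.05,t4:0.07):0.05):0.05,"
    "((t5:0.08,t6:0.04):0.06,(t7:0.05,t8:0.09):0.04):0.05);"
)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not serializable: {type(obj)}")


def save_config(config, seed: int, path) -> None:
    """Serialize a generator config plus its seed next to the outputs."""
    payload = {"seed": seed, "config": dataclasses.asdict(config)}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


# ---------------------------------------------------------------------------
# Codon alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class AlignmentSimConfig:
    """Conditions for the codon-alignment generator.

    ``multipliers`` are relative per-site rates for the six substitution
    cells in :data:`lepcodon.rates.CELLS` order; 1.0 everywhere is an
    unbiased neutral process.  ``gc1``/``gc2``/``gc3`` set the root
    composition per codon position.
    """

    newick: str = DEFAULT_TREE
    n_genes: int = 10
    gene_length_codons: int = 300
    gc1: float = 0.51
    gc2: float = 0.39
    gc3: float = 0.47
    multipliers: dict = field(
        default_factory=lambda: {cell: 1.0 for cell in CELLS}
    )


def stationary_codon_weights(gc1: float, gc2: float, gc3: float) -> dict[str, float]:
    """Sense-codon weights from independent per-position base compositions."""
    code = standard_code()
    probs = []
    for gc in (gc1, gc2, gc3):
        probs.append({"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2})
    w = {}
    for codon in code.sense_codons:
        w[codon] = probs[0][codon[0]] * probs[1][codon[1]] * probs[2][codon[2]]
    total = sum(w.values())
    return {c: v / total for c, v in w.items()}


def random_coding_sequence(rng: np.random.Generator, n_codons: int, gc3: float = 0.47,
                           gc1: float = 0.51, gc2: float = 0.39) -> str:
    """A random in-frame sequence drawn from compositional codon weights."""
    w = stationary_codon_weights(gc1, gc2, gc3)
    codons = list(w)
    p = np.array([w[c] for c in codons])
    idx = rng.choice(len(codons), size=n_codons, p=p)
    return "".join(codons[i] for i in idx)


def compositional_gene(rng: np.random.Generator, n_codons: int, gc3: float) -> str:
    """Gene whose codon choice within each family follows third-base composition.

    Amino acids are drawn uniformly; the codon within the family is chosen
    proportional to the third-base composition implied by ``gc3``.  Under
    this process codon usage bias beyond composition is absent, so
    ENC_diff is centered on zero.
    """
    code = standard_code()
    p3 = {"G": gc3 / 2, "C": gc3 / 2, "A": (1 - gc3) / 2, "T": (1 - gc3) / 2}
    aas = code.amino_acids
    out = []
    for _ in range(n_codons):
        aa = aas[rng.integers(len(aas))]
        fam = code.families[aa]
        w = np.array([p3[c[2]] for c in fam])
        out.append(fam[rng.choice(len(fam), p=w / w.sum())])
    return "".join(out)


from functools import lru_cache


@lru_cache(maxsize=None)
def _codon_neighbors(codon: str) -> tuple[tuple[str, int], ...]:
    """Non-stop single-base neighbors with their cell indices (cached)."""
    code = standard_code()
    out = []
    for _, _, nb in all_single_neighbors(codon):
        if code.is_stop(nb):
            continue
        out.append((nb, CELL_INDEX[single_step_class(codon, nb, code)]))
    return tuple(out)


def _evolve_codon(codon: str, t: float, mult: np.ndarray, rng: np.random.Generator):
    """Gillespie evolution of one codon for branch length t (subs/site at rate 1).

    Each single-base change to a non-stop neighbor occurs at rate
    mult[cell] / 3, so an all-ones multiplier vector gives ≈1 expected
    substitution per nucleotide site per unit branch length.  Returns the
    final codon and the list of cell indices of the events.
    """
    events = []
    clock = 0.0
    current = codon
    while True:
        nbs = _codon_neighbors(current)
        rates = np.array([mult[cell] for _, cell in nbs]) / 3.0
        total = rates.sum()
        if total == 0:
            break
        clock += rng.exponential(1.0 / total)
        if clock >= t:
            break
        k = rng.choice(len(nbs), p=rates / total)
        current, cell_idx = nbs[k]
        events.append(cell_idx)
    return current, events


def simulate_alignment(config: AlignmentSimConfig, rng: np.random.Generator,
                       gene_id: str = "gene"):
    """Evolve one gene along the tree; returns (alignment, truth, tree).

    ``truth`` maps branch id (child node) → 6-vector of true event counts
    per cell, plus the ancestral sequence of every node under
    ``truth["_sequences"]``.
    """
    tree = load_tree(config.newick)
    mult = np.array([config.multipliers.get(cell, 1.0) for cell in CELLS])
    root_seq = random_coding_sequence(
        rng, config.gene_length_codons, config.gc3, config.gc1, config.gc2
    )
    seqs = {}
    truth: dict[str, np.ndarray] = {}
    node_seq = {tree.seed_node.node_id: root_seq}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_seq = node_seq[node.parent_node.node_id]
        t = node.edge.length or 0.0
        counts = np.zeros(len(CELLS))
        if t == 0:
            child = parent_seq
        else:
            codons = []
            for i in range(0, len(parent_seq), 3):
                c, events = _evolve_codon(parent_seq[i:i + 3], t, mult, rng)
                codons.append(c)
                for e in events:
                    counts[e] += 1
            child = "".join(codons)
        node_seq[node.node_id] = child
        truth[node.node_id] = counts
    for leaf in tree.leaf_node_iter():
        seqs[leaf.taxon.label] = node_seq[leaf.node_id]
    aln = CodonAlignment(gene_id, [l.taxon.label for l in tree.leaf_node_iter()], seqs)
    truth["_sequences"] = node_seq
    return aln, truth, tree


def simulate_branch_pair(config: AlignmentSimConfig, rng: np.random.Generator,
                         branch_length: float = 0.1, gene_id: str = "gene"):
    """Ancestor/descendant pair along a single branch with true event counts."""
    mult = np.array([config.multipliers.get(cell, 1.0) for cell in CELLS])
    anc = random_coding_sequence(
        rng, config.gene_length_codons, config.gc3, config.gc1, config.gc2
    )
    counts = np.zeros(len(CELLS))
    codons = []
    for i in range(0, len(anc), 3):
        c, events = _evolve_codon(anc[i:i + 3], branch_length, mult, rng)
        codons.append(c)
        for e in events:
            counts[e] += 1
    return anc, "".join(codons), counts


# ---------------------------------------------------------------------------
# Planted QC batches
# ---------------------------------------------------------------------------

@dataclass
class QCBatchConfig:
    n_clean: int = 6
    n_taxa: int = 8
    clean_length_codons: int = 150


def simulate_qc_batch(config: QCBatchConfig, rng: np.random.Generator):
    """Alignment batch with one planted violation per rule.

    Returns (alignments, truth) where truth maps gene id → planted
    violation label ("clean", "short", "interspersed_stop",
    "frameshift_gap", "missing_lineage", "mean_gap").
    """
    taxa = [f"t{i+1}" for i in range(config.n_taxa)]

    def clean_gene(n_codons):
        base = random_coding_sequence(rng, n_codons)
        seqs = {}
        code = standard_code()
        for t in taxa:
            s = list(base)
            for _ in range(max(1, n_codons // 50)):  # sprinkle substitutions
                j = rng.integers(n_codons)
                codon = "".join(s[3 * j:3 * j + 3])
                nbs = [nb for _, _, nb in all_single_neighbors(codon) if code.is_sense(nb)]
                s[3 * j:3 * j + 3] = list(nbs[rng.integers(len(nbs))])
            seqs[t] = "".join(s)
        return seqs

    alignments, truth = [], {}
    gid = 0

    def add(label, seqs):
        nonlocal gid
        gene = f"g{gid:03d}"
        gid += 1
        alignments.append(CodonAlignment(gene, list(taxa), seqs))
        truth[gene] = label

    for _ in range(config.n_clean):
        add("clean", clean_gene(config.clean_length_codons))

    # Too short after trimming (< 100 codons).
    add("short", clean_gene(80))

    # Interspersed stop codon in one lineage.
    seqs = clean_gene(config.clean_length_codons)
    victim = taxa[int(rng.integers(len(taxa)))]
    s = list(seqs[victim])
    j = int(rng.integers(1, config.clean_length_codons - 1))
    s[3 * j:3 * j + 3] = list("TAA")
    seqs[victim] = "".join(s)
    add("interspersed_stop", seqs)

    # Gap run whose length is not a multiple of three.
    seqs = clean_gene(config.clean_length_codons)
    victim = taxa[int(rng.integers(len(taxa)))]
    s = list(seqs[victim])
    start = int(rng.integers(3, len(s) - 10))
    s[start:start + 4] = list("----")
    seqs[victim] = "".join(s)
    add("frameshift_gap", seqs)

    # One lineage with >50% missing codons (columns stay below the 50%
    # trimming threshold because only one of n_taxa lineages is gapped).
    seqs = clean_gene(config.clean_length_codons)
    victim = taxa[0]
    n = config.clean_length_codons
    gap_cols = rng.choice(n, size=int(0.6 * n), replace=False)
    s = list(seqs[victim])
    for j in gap_cols:
        s[3 * j:3 * j + 3] = list("---")
    seqs[victim] = "".join(s)
    add("missing_lineage", seqs)

    # Mean per-sequence gap fraction > 25% with every column at 3/8 gaps
    # (below both the 50% column-trim and per-lineage thresholds).
    n = config.clean_length_codons
    seqs = clean_gene(n)
    k = 3  # gapped lineages per column -> mean gap fraction 3/8 = 0.375
    mat = {t: list(seqs[t]) for t in taxa}
    for j in range(n):
        for m in range(k):
            t = taxa[(j + m) % len(taxa)]
            mat[t][3 * j:3 * j + 3] = list("---")
    add("mean_gap", {t: "".join(v) for t, v in mat.items()})

    return alignments, truth


def simulate_rate_table(rng: np.random.Generator, n_clean: int = 10):
    """Per-gene (dS, ω) table with planted saturation / unbounded-ω outliers."""
    rows, truth = [], {}
    for i in range(n_clean):
        g = f"r{i:03d}"
        rows.append({"gene": g, "ds": float(rng.uniform(0.05, 2.0)),
                     "omega": float(rng.uniform(0.02, 0.5))})
        truth[g] = "clean"
    rows.append({"gene": "r_sat", "ds": float(rng.uniform(30.5, 80.0)),
                 "omega": 0.1})
    truth["r_sat"] = "ds_saturated"
    rows.append({"gene": "r_inf", "ds": 0.2, "omega": 999.0})
    truth["r_inf"] = "omega_unbounded"
    return rows, truth


# ---------------------------------------------------------------------------
# Polymorphism simulation
# ---------------------------------------------------------------------------

@dataclass
class PopgenSimConfig:
    """Study conditions for the polymorphism generator.

    Defaults emulate the genome-wide 4-fold degenerate sites of a
    butterfly population sample of 10 diploid individuals (n = 20
    chromosomes): 1e6 sites with GC = 0.45 (L_S = 4.5e5 strong,
    L_W = 5.5e5 weak), per-weak-site W→S scaled mutation intensity 0.01
    (≈1% synonymous diversity), mutation bias λ applied to the S→W
    class, and a GC-conservative class at the same per-site intensity
    over all sites.  Use :meth:`zerofold_conditions` for the 0-fold
    analogue (more sites, diversity reduced ~5× by constraint).
    """

    n: int = 20
    B: float = 0.46
    lam: float = 2.96
    L_W: float = 5.5e5
    L_S: float = 4.5e5
    mu_site: float = 0.01          # scaled W->S intensity per weak site
    mu_cons_site: float = 0.01     # conservative intensity per site
    polarization_error: float = 0.0
    distortion: np.ndarray | None = None  # planted r_i, mean 1

    @classmethod
    def fourfold_conditions(cls) -> "PopgenSimConfig":
        """4-fold degenerate-site conditions (the defaults, spelled out)."""
        return cls()

    @classmethod
    def zerofold_conditions(cls) -> "PopgenSimConfig":
        """0-fold degenerate-site conditions: B = 0.56, λ = 2.73.

        0-fold sites outnumber 4-fold sites roughly 2:1 in coding
        sequence, and purifying selection depresses their diversity;
        intensities are set 5× lower than at 4-fold sites.
        """
        return cls(B=0.56, lam=2.73, L_W=3.3e6, L_S=2.7e6,
                   mu_site=0.002, mu_cons_site=0.002)

    @property
    def theta_WS(self) -> float:
        return self.mu_site * self.L_W

    @property
    def theta_SW(self) -> float:
        return self.lam * self.mu_site * self.L_S

    @property
    def theta_cons(self) -> float:
        return self.mu_cons_site * (self.L_W + self.L_S)


def expected_class_spectra(config: PopgenSimConfig) -> dict[str, np.ndarray]:
    """Poisson bin intensities per mutation class under the config."""
    n, e = config.n, config.polarization_error
    r = config.distortion if config.distortion is not None else np.ones(n - 1)
    return {
        "WS": r * config.theta_WS * _mix(sfs_shape(+config.B, n), e),
        "SW": r * config.theta_SW * _mix(sfs_shape(-config.B, n), e),
        "conservative": r * config.theta_cons * _mix(sfs_shape(0.0, n), e),
    }


def simulate_polymorphism(config: PopgenSimConfig, rng: np.random.Generator):
    """Sample class spectra: counts c_i ~ Poisson(r_i θ_class E_i(±B)).

    Returns (spectra dict class → counts array, expected intensities).
    """
    expected = expected_class_spectra(config)
    spectra = {cls: rng.poisson(mu).astype(float) for cls, mu in expected.items()}
    return spectra, expected


# --- VCF / FASTA / GFF fixtures -------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _pick_derived(base: str, mclass: str, rng: np.random.Generator) -> str:
    strong, weak = ["C", "G"], ["A", "T"]
    cls = classify_base(base)
    if mclass == "WS":
        pool = strong
    elif mclass == "SW":
        pool = weak
    else:
        pool = [b for b in (strong if cls == "S" else weak) if b != base]
    return pool[int(rng.integers(len(pool)))]


def simulate_polymorphism_fixtures(
    config: PopgenSimConfig,
    outdir,
    rng: np.random.Generator,
    n_genes: int = 30,
    gene_length_codons: int = 120,
    degeneracy: int = 4,
):
    """Write VCF + reference FASTA + GFF3 + outgroup-TSV fixtures.

    A small genome of ``n_genes`` CDSs (the last one on the minus strand)
    is built; segregating sites are planted at sites of the requested
    degeneracy class by drawing bin counts from spectra scaled to the
    number of available candidate sites.  The reference allele is the
    ancestral state; with probability ``polarization_error`` both
    outgroups carry the derived base instead, inverting polarization.

    Returns (paths dict, planted PolarizedSite truth list).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    code = standard_code()
    n = config.n

    spacer = "T" * 60
    chrom = "chr1"
    genes = []  # (gene_id, start_1based, end_1based, strand, cds_seq)
    genome_parts = [spacer]
    pos = len(spacer)
    for g in range(n_genes):
        cds = random_coding_sequence(rng, gene_length_codons, gc3=0.45)
        strand = "-" if g == n_genes - 1 else "+"
        genomic = reverse_complement(cds) if strand == "-" else cds
        start = pos + 1
        end = pos + len(genomic)
        genes.append((f"g{g:03d}", start, end, strand, cds))
        genome_parts.append(genomic)
        genome_parts.append(spacer)
        pos = end + len(spacer)
    genome = "".join(genome_parts)

    # Candidate sites of the requested degeneracy, keyed by base class.
    candidates = {"S": [], "W": []}
    for gene_id, start, end, strand, cds in genes:
        for idx in range(len(cds)):
            codon_i, within = divmod(idx, 3)
            codon = cds[3 * codon_i:3 * codon_i + 3]
            if not code.is_sense(codon):
                continue
            if code.site_degeneracy(codon, within + 1) != degeneracy:
                continue
            if strand == "+":
                gpos = start + idx
            else:
                gpos = end - idx
            candidates[classify_base(cds[idx])].append(
                (gene_id, gpos, codon, within + 1, cds[idx], strand)
            )
    # Scale spectra intensities to the miniature genome.
    scale = {
        "WS": len(candidates["W"]) / config.L_W,
        "SW": len(candidates["S"]) / config.L_S,
        "conservative": (len(candidates["W"]) + len(candidates["S"]))
        / (config.L_W + config.L_S),
    }
    expected = expected_class_spectra(config)
    pools = {"WS": list(candidates["W"]), "SW": list(candidates["S"]),
             "conservative": list(candidates["W"]) + list(candidates["S"])}
    for cls in pools:
        rng.shuffle(pools[cls])

    truth: list[PolarizedSite] = []
    vcf_rows = []
    outgroup_rows = []
    used_positions = set()
    for cls in ("WS", "SW", "conservative"):
        mu = expected[cls] * scale[cls]
        counts = rng.poisson(mu)
        pool = pools[cls]
        for i_bin, c in enumerate(counts, start=1):
            for _ in range(int(c)):
                while pool and (pool[-1][1] in used_positions):
                    pool.pop()
                if not pool:
                    break
                gene_id, gpos, codon, cpos, anc_cds, strand = pool.pop()
                used_positions.add(gpos)
                der_cds = _pick_derived(anc_cds, cls, rng)
                # genome-strand representation
                if strand == "-":
                    anc_g, der_g = reverse_complement(anc_cds), reverse_complement(der_cds)
                else:
                    anc_g, der_g = anc_cds, der_cds
                carriers = rng.choice(n, size=i_bin, replace=False)
                gts = []
                for d in range(n // 2):
                    a1 = 1 if 2 * d in carriers else 0
                    a2 = 1 if 2 * d + 1 in carriers else 0
                    gts.append(f"{a1}|{a2}")
                flipped = rng.random() < config.polarization_error
                out_base = der_g if flipped else anc_g
                vcf_rows.append((gpos, anc_g, der_g, gts))
                outgroup_rows.append((gpos, out_base, out_base))
                truth.append(
                    PolarizedSite(
                        site_id=f"{chrom}:{gpos}",
                        codon=codon,
                        codon_position=cpos,
                        degeneracy=degeneracy,
                        ancestral=anc_cds,
                        derived=der_cds,
                        derived_count=i_bin,
                        n=n,
                        mutation_class=cls,
                    )
                )

    paths = {
        "fasta": outdir / "reference.fa",
        "gff": outdir / "annotation.gff3",
        "vcf": outdir / "variants.vcf",
        "outgroups": outdir / "outgroups.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), 80):
            fh.write(genome[i:i + 80] + "\n")
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, start, end, strand, _ in genes:
            fh.write(
                f"{chrom}\tlepcodon_sim\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
                f"ID=cds_{gene_id};Parent={gene_id}\n"
            )
    samples = [f"ind{d+1}" for d in range(n // 2)]
    with open(paths["vcf"], "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(f"##contig=<ID={chrom},length={len(genome)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for gpos, ref, alt, gts in sorted(vcf_rows):
            fh.write(f"{chrom}\t{gpos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    with open(paths["outgroups"], "w") as fh:
        fh.write("#chrom\tpos\toutgroup1\toutgroup2\n")
        for gpos, b1, b2 in sorted(outgroup_rows):
            fh.write(f"{chrom}\t{gpos}\t{b1}\t{b2}\n")
    return paths, truth


# ---------------------------------------------------------------------------
# tRNAscan-SE fixtures
# ---------------------------------------------------------------------------

@dataclass
class TRNASimConfig:
    """Planted tRNA repertoire: copies per anticodon plus decoy rows."""

    copies: dict = field(
        default_factory=lambda: {"GCC": 7, "AAT": 3, "TGC": 5, "CAA": 2, "GAA": 4}
    )
    n_pseudo: int = 2
    n_truncated: int = 1
    outlier: tuple | None = None  # e.g. ("GGT", 57)
    minus_strand_fraction: float = 0.3


_HEADER = (
    "Sequence\t\ttRNA\tBounds\t\ttRNA\tAnti\tIntron Bounds\tInf\t\n"
    "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote\n"
    "--------\t------\t-----\t----\t----\t-----\t-----\t---\t-----\t----\n"
)


def simulate_trnascan_fixture(config: TRNASimConfig, rng: np.random.Generator):
    """Syntactically valid tRNAscan-SE 2.x table text with planted truth.

    Returns (text, truth) where truth = {"functional_copies": {...},
    "n_pseudo": ..., "n_truncated": ...}.
    """
    code = standard_code()
    rows = []
    counter = 1
    pos = 1000
    copies = dict(config.copies)
    if config.outlier:
        ac, k = config.outlier
        copies[ac] = copies.get(ac, 0) + k

    def aa_name(anticodon):
        aa = code.translate(reverse_complement(anticodon))
        names = {
            "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
            "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
            "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
            "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
        }
        return names.get(aa, "Undet")

    def emit(anticodon, note=""):
        nonlocal counter, pos
        length = 72
        begin, end = pos, pos + length
        if rng.random() < config.minus_strand_fraction:
            begin, end = end, begin  # minus strand: inverted coordinates
        score = round(float(rng.uniform(40, 90)), 1)
        rows.append(
            f"chr1\t{counter}\t{begin}\t{end}\t{aa_name(anticodon)}\t"
            f"{anticodon}\t0\t0\t{score}\t{note}"
        )
        counter += 1
        pos += 500

    for ac, k in sorted(copies.items()):
        for _ in range(k):
            emit(ac)
    for _ in range(config.n_pseudo):
        emit("GCC", note="pseudo")
    for _ in range(config.n_truncated):
        emit("AAT", note="trunc_start:10")

    truth = {
        "functional_copies": copies,
        "n_pseudo": config.n_pseudo,
        "n_truncated": config.n_truncated,
    }
    return _HEADER + "\n".join(rows) + "\n", truth
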