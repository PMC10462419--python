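"""Polarized site spectra and the gBGC–mutation–drift equilibrium fit.

The analysis chain: polarize biallelic SNPs against two outgroup alleles
by parsimony, classify each site by degeneracy (0-fold / 4-fold) and
mutation direction (W→S, S→W, GC-conservative), bin derived-allele counts
into unfolded site-frequency spectra (SFS), and fit an equilibrium model
of GC-biased gene conversion to estimate

* ``B`` = 4·N_e·b — the population-scaled conversion (fixation-bias)
  coefficient, acting like a selection coefficient favoring the strong
  (G/C) allele: W→S derived alleles experience +B, S→W derived alleles −B,
  conservative changes 0;
* ``λ`` — the S→W over W→S per-site mutation-rate ratio, obtained from the
  fitted class mutation intensities normalized by the numbers of
  monomorphic strong (L_S) and weak (L_W) sites.

The expected unfolded spectrum at sample size n is

    E_i(θ, B) = θ · C(n,i) ∫₀¹ x^i (1−x)^{n−i}
                · (1 − e^{−B(1−x)}) / ((1 − e^{−B}) · x(1−x)) dx ,

the classic semidominant fixed-coefficient diffusion result, with the
neutral limit E_i = θ/i as B → 0.  The likelihood is composite Poisson per
frequency bin with per-bin distortion nuisances r_i shared across the
three mutation classes and anchored by the GC-conservative (neutral-
direction) class — absorbing demography and ascertainment distortions
that affect all classes alike.  Optional polarization error e mixes each
spectrum with its frequency-reversed image.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize, special

from .genetics import GeneticCode, classify_base, mutation_class, reverse_complement, standard_code

__all__ = [
    "PolarizedSite",
    "ClassSFS",
    "GbgcFit",
    "polarize",
    "classify_site",
    "build_sfs",
    "monomorphic_class_counts",
    "expected_sfs",
    "sfs_shape",
    "fit_gbgc",
    "bootstrap_fit",
    "extract_polarized_sites",
]

_B_TINY = 1e-8
_B_BOUND = 50.0


# ---------------------------------------------------------------------------
# Site polarization and classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolarizedSite:
    """One polarized biallelic coding SNP."""

    site_id: str
    codon: str              # ancestral codon context
    codon_position: int     # 1..3
    degeneracy: int         # 0, 2, 3 or 4
    ancestral: str
    derived: str
    derived_count: int      # 1..n-1
    n: int                  # sampled chromosomes
    mutation_class: str     # "WS", "SW" or "conservative"


def polarize(
    ingroup_alleles: dict[str, int],
    outgroup1: str | None,
    outgroup2: str | None,
    relaxed: bool = True,
) -> tuple[str, str, int] | None:
    """Parsimony polarization of a biallelic site against two outgroups.

    The ancestral allele is the ingroup allele matched by both outgroups;
    in ``relaxed`` mode a single available outgroup suffices when the
    other is missing.  Discordant or uninformative outgroups yield None
    (site excluded, counted by the caller).

    Returns (ancestral, derived, derived_count).
    """
    alleles = [a for a, c in ingroup_alleles.items() if c > 0]
    if len(alleles) != 2:
        raise ValueError(f"site is not biallelic in the ingroup: {ingroup_alleles}")
    outs = [o.upper() for o in (outgroup1, outgroup2) if o and o.upper() in "ACGT"]
    if not outs:
        return None
    if len(outs) == 1 and not relaxed:
        return None
    anc_candidates = {o for o in outs}
    if len(anc_candidates) > 1:
        return None  # outgroups disagree
    anc = anc_candidates.pop()
    if anc not in alleles:
        return None  # outgroup matches neither segregating allele
    der = alleles[0] if alleles[1] == anc else alleles[1]
    return anc, der, ingroup_alleles[der]


def classify_site(
    codon: str,
    position: int,
    anc: str,
    der: str,
    code: GeneticCode | None = None,
) -> tuple[int | None, str]:
    """(degeneracy class, mutation class) of a polarized coding SNP.

    Degeneracy is taken from the ancestral codon context: the codon with
    the ancestral base substituted at ``position``.  Sites that are
    neither 0-fold nor 4-fold return degeneracy None (excluded from the
    bias analysis but still classified by direction).
    """
    code = code or standard_code()
    idx = position - 1
    anc_codon = codon[:idx] + anc.upper() + codon[idx + 1:]
    if not code.is_sense(anc_codon):
        return None, mutation_class(anc, der)
    deg = code.site_degeneracy(anc_codon, position)
    if deg not in (0, 4):
        return None, mutation_class(anc, der)
    return deg, mutation_class(anc, der)


@dataclass
class ClassSFS:
    """Unfolded SFS of one mutation class at one degeneracy class."""

    mutation_class: str
    degeneracy: int
    counts: np.ndarray          # length n-1, bins i = 1 .. n-1
    n: int
    L_W: float = 0.0            # monomorphic weak sites of the class
    L_S: float = 0.0            # monomorphic strong sites

    @property
    def segregating(self) -> float:
        return float(self.counts.sum())


def build_sfs(sites: list[PolarizedSite], n: int) -> dict[tuple[str, int], ClassSFS]:
    """Bin polarized sites into per-(mutation class × degeneracy) spectra."""
    out: dict[tuple[str, int], ClassSFS] = {}
    for s in sites:
        if s.degeneracy is None:
            continue
        if not 0 < s.derived_count < n:
            continue
        key = (s.mutation_class, s.degeneracy)
        if key not in out:
            out[key] = ClassSFS(s.mutation_class, s.degeneracy, np.zeros(n - 1), n)
        out[key].counts[s.derived_count - 1] += 1
    return out


def monomorphic_class_counts(cds_sequences, code: GeneticCode | None = None) -> dict[int, dict[str, int]]:
    """Count 0-fold and 4-fold S and W sites in reference CDS sequences.

    Returns ``{degeneracy: {"S": count, "W": count}}``; used as L_S / L_W
    normalizers for the mutation-bias ratio.
    """
    code = code or standard_code()
    if isinstance(cds_sequences, str):
        cds_sequences = [cds_sequences]
    out = {0: {"S": 0, "W": 0}, 4: {"S": 0, "W": 0}}
    for seq in cds_sequences:
        s = seq.upper()
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i:i + 3]
            if not code.is_sense(codon):
                continue
            for pos in (1, 2, 3):
                deg = code.site_degeneracy(codon, pos)
                if deg in (0, 4):
                    out[deg][classify_base(codon[pos - 1])] += 1
    return out


# ---------------------------------------------------------------------------
# Expected SFS under gBGC-mutation-drift equilibrium
# ---------------------------------------------------------------------------

def _h(x: np.ndarray, B: float) -> np.ndarray:
    """(1 − e^{−B(1−x)}) / (1 − e^{−B}), the sojourn-density bias factor."""
    if abs(B) < _B_TINY:
        return 1.0 - x
    return np.expm1(-B * (1.0 - x)) / np.expm1(-B)


def expected_sfs(theta: float, B: float, n: int) -> np.ndarray:
    """Expected unfolded SFS counts E_1..E_{n−1} by adaptive quadrature.

    ``B`` is the population-scaled conversion coefficient experienced by
    the *derived* allele (+B for W→S, −B for S→W, 0 conservative); θ is
    the class mutation intensity.  For |B| below 1e−8 the analytic
    neutral limit E_i = θ/i is returned.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if n < 2:
        raise ValueError("need at least 2 sampled chromosomes")
    if abs(B) > _B_BOUND:
        raise ValueError(f"|B| > {_B_BOUND} is outside the supported range")
    i_arr = np.arange(1, n)
    if abs(B) < _B_TINY:
        return theta / i_arr
    out = np.empty(n - 1)
    for k, i in enumerate(i_arr):
        # integrand: C(n,i) x^{i-1} (1-x)^{n-i-1} h_B(x); smooth on [0,1]
        coef = special.comb(n, i, exact=False)

        def f(x, i=i, coef=coef):
            return coef * x ** (i - 1) * (1.0 - x) ** (n - i - 1) * _h(np.asarray(x), B)

        val, err = integrate.quad(f, 0.0, 1.0, epsabs=1e-12, epsrel=1e-10, limit=200)
        if not np.isfinite(val):
            raise ArithmeticError(f"quadrature failed for i={i}, B={B}, n={n}")
        out[k] = val
    return theta * out


@lru_cache(maxsize=32)
def _gl_grid(n: int, order: int = 256):
    """Gauss–Legendre nodes on (0,1) and the binomial kernel matrix for n."""
    x, w = np.polynomial.legendre.leggauss(order)
    x = 0.5 * (x + 1.0)
    w = 0.5 * w
    i_arr = np.arange(1, n)
    coef = special.comb(n, i_arr, exact=False)
    # M[i-1, k] = C(n,i) x_k^{i-1} (1-x_k)^{n-i-1} w_k
    M = (
        coef[:, None]
        * x[None, :] ** (i_arr[:, None] - 1)
        * (1.0 - x[None, :]) ** (n - i_arr[:, None] - 1)
        * w[None, :]
    )
    return x, M


def sfs_shape(B: float, n: int) -> np.ndarray:
    """E_i(θ=1, B) on a fixed Gauss–Legendre grid (fast path for fitting).

    Agrees with :func:`expected_sfs` to well below 1e−9 relative for the
    smooth integrands involved; used inside the likelihood loop where the
    shape is evaluated thousands of times.
    """
    if abs(B) < _B_TINY:
        return 1.0 / np.arange(1, n)
    x, M = _gl_grid(n)
    return M @ _h(x, B)


# ---------------------------------------------------------------------------
# Maximum-likelihood fit
# ---------------------------------------------------------------------------

@dataclass
class GbgcFit:
    """Point estimates and diagnostics of the equilibrium-model fit."""

    B: float
    lam: float
    theta_WS: float
    theta_SW: float
    theta_cons: float
    e: float
    r: np.ndarray
    loglik: float
    n: int
    L_W: float
    L_S: float
    converged: bool
    n_iter: int
    boundary: bool = False
    bootstrap: dict = field(default_factory=dict)


def _mix(shape: np.ndarray, e: float) -> np.ndarray:
    """Polarization-error mixture: (1−e)·E_i + e·E_{n−i}."""
    if e == 0.0:
        return shape
    return (1.0 - e) * shape + e * shape[::-1]


def _poisson_loglik(counts: np.ndarray, mean: np.ndarray) -> float:
    mean = np.maximum(mean, 1e-300)
    return float(np.sum(counts * np.log(mean) - mean))


def _class_shapes(B: float, e: float, n: int) -> dict[str, np.ndarray]:
    neutral = 1.0 / np.arange(1, n)
    return {
        "WS": _mix(sfs_shape(+B, n), e),
        "SW": _mix(sfs_shape(-B, n), e),
        "conservative": _mix(neutral, e),
    }


def _profile_theta(counts: dict[str, np.ndarray], shapes: dict[str, np.ndarray], r: np.ndarray) -> dict[str, float]:
    out = {}
    for cls, c in counts.items():
        denom = float(np.sum(r * shapes[cls]))
        out[cls] = float(c.sum()) / denom if denom > 0 else 1e-12
    return out


def _total_loglik(counts, shapes, theta, r) -> float:
    return sum(
        _poisson_loglik(counts[cls], r * theta[cls] * shapes[cls]) for cls in counts
    )


def fit_gbgc(
    sfs_WS: np.ndarray,
    sfs_SW: np.ndarray,
    sfs_cons: np.ndarray,
    L_W: float,
    L_S: float,
    n: int | None = None,
    fit_error: bool = False,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> GbgcFit:
    """Maximum-likelihood fit of (θ_WS, θ_SW, θ_cons, B, r_i[, e]).

    Poisson composite likelihood per frequency bin; shared distortion
    terms r_i (normalized to mean 1) are driven mostly by the
    GC-conservative class, which is unaffected by B and so anchors them.
    Optimization is coordinate ascent: closed-form θ and r updates
    alternate with a profiled 1-D line search over B (and e when
    ``fit_error``); every step is monotone in the likelihood.  Two starts
    (positive and negative B) guard against the B ↔ −B likelihood ridge
    at extreme distortions.

    λ is derived as (θ_SW / L_S) / (θ_WS / L_W): the per-strong-site S→W
    intensity over the per-weak-site W→S intensity.

    The spectra must share the same sample size n (inferred from the
    vector length when not given).
    """
    counts = {
        "WS": np.asarray(sfs_WS, dtype=float),
        "SW": np.asarray(sfs_SW, dtype=float),
        "conservative": np.asarray(sfs_cons, dtype=float),
    }
    lengths = {len(v) for v in counts.values()}
    if len(lengths) != 1:
        raise ValueError("all spectra must have the same number of bins")
    nbins = lengths.pop()
    n = n or nbins + 1
    if n != nbins + 1:
        raise ValueError(f"spectra of length {nbins} imply n={nbins+1}, got n={n}")
    if L_W <= 0 or L_S <= 0:
        raise ValueError("L_W and L_S must be positive")
    if all(v.sum() == 0 for v in counts.values()):
        raise ValueError("all spectra are empty; nothing to fit")

    def run(B0: float) -> tuple[float, float, float, dict, np.ndarray, int, bool]:
        B, e = B0, 0.0
        r = np.ones(nbins)
        shapes = _class_shapes(B, e, n)
        theta = _profile_theta(counts, shapes, r)
        ll = _total_loglik(counts, shapes, theta, r)
        it = 0
        converged = False
        for it in range(1, max_iter + 1):
            # r update (closed form), then renormalize to mean 1
            num = sum(counts[cls] for cls in counts)
            den = sum(theta[cls] * shapes[cls] for cls in counts)
            r = np.where(den > 0, num / np.maximum(den, 1e-300), 1.0)
            scale = r.mean()
            if scale <= 0:
                break
            r = r / scale
            theta = {cls: t * scale for cls, t in theta.items()}

            # B update with theta profiled out
            def neg_ll_B(Bval):
                sh = _class_shapes(Bval, e, n)
                th = _profile_theta(counts, sh, r)
                return -_total_loglik(counts, sh, th, r)

            res = optimize.minimize_scalar(
                neg_ll_B, bounds=(-10.0, 10.0), method="bounded",
                options={"xatol": 1e-10},
            )
            B = float(res.x)

            if fit_error:
                def neg_ll_e(eval_):
                    sh = _class_shapes(B, eval_, n)
                    th = _profile_theta(counts, sh, r)
                    return -_total_loglik(counts, sh, th, r)

                res_e = optimize.minimize_scalar(
                    neg_ll_e, bounds=(0.0, 0.499), method="bounded",
                    options={"xatol": 1e-10},
                )
                e = float(res_e.x)

            shapes = _class_shapes(B, e, n)
            theta = _profile_theta(counts, shapes, r)
            new_ll = _total_loglik(counts, shapes, theta, r)
            if abs(new_ll - ll) < tol * (1.0 + abs(ll)):
                ll = new_ll
                converged = True
                break
            ll = new_ll
        return ll, B, e, theta, r, it, converged

    best = max((run(B0) for B0 in (0.5, -0.5)), key=lambda t: t[0])
    ll, B, e, theta, r, n_iter, converged = best
    lam = (theta["SW"] / L_S) / (theta["WS"] / L_W)
    boundary = abs(abs(B) - 10.0) < 1e-6
    if boundary:
        warnings.warn("B estimate is at the optimization bound", RuntimeWarning)
    return GbgcFit(
        B=B, lam=lam,
        theta_WS=theta["WS"], theta_SW=theta["SW"], theta_cons=theta["conservative"],
        e=e, r=r, loglik=ll, n=n, L_W=L_W, L_S=L_S,
        converged=converged, n_iter=n_iter, boundary=boundary,
    )


def bootstrap_fit(
    sfs_WS: np.ndarray,
    sfs_SW: np.ndarray,
    sfs_cons: np.ndarray,
    L_W: float,
    L_S: float,
    n_boot: int = 1000,
    seed: int = 0,
    fit_error: bool = False,
    ci: float = 0.95,
) -> GbgcFit:
    """Fit with site-resampling bootstrap percentile CIs for B and λ.

    Segregating sites are resampled with replacement jointly across the
    three classes (multinomial over all bins, total site count fixed);
    monomorphic counts L_W and L_S stay fixed.  More than 5% failed refits
    sets a warning flag in the fit metadata.
    """
    fit = fit_gbgc(sfs_WS, sfs_SW, sfs_cons, L_W, L_S, fit_error=fit_error)
    rng = np.random.default_rng(seed)
    flat = np.concatenate([np.asarray(v, float) for v in (sfs_WS, sfs_SW, sfs_cons)])
    total = flat.sum()
    probs = flat / total
    nbins = len(np.asarray(sfs_WS))
    B_vals, lam_vals, failures = [], [], 0
    for _ in range(n_boot):
        draw = rng.multinomial(int(round(total)), probs)
        ws, sw, cons = draw[:nbins], draw[nbins:2 * nbins], draw[2 * nbins:]
        try:
            f = fit_gbgc(ws, sw, cons, L_W, L_S, fit_error=fit_error)
            if not f.converged:
                failures += 1
                continue
            B_vals.append(f.B)
            lam_vals.append(f.lam)
        except (ValueError, ArithmeticError):
            failures += 1
    alpha = (1.0 - ci) / 2
    def _ci(vals):
        return (
            float(np.quantile(vals, alpha)),
            float(np.quantile(vals, 1.0 - alpha)),
        ) if vals else (math.nan, math.nan)

    fit.bootstrap = {
        "n_boot": n_boot,
        "seed": seed,
        "ci_level": ci,
        "n_failures": failures,
        "failure_warning": failures > 0.05 * n_boot,
        "B_ci": _ci(B_vals),
        "lambda_ci": _ci(lam_vals),
        "B_samples": np.asarray(B_vals),
        "lambda_samples": np.asarray(lam_vals),
    }
    return fit


# ---------------------------------------------------------------------------
# VCF + FASTA + GFF3 extraction
# ---------------------------------------------------------------------------

def _read_gff_cds(gff_path) -> dict[str, list[tuple[str, int, int, str]]]:
    """Minimal GFF3 CDS reader: gene_id -> [(chrom, start, end, strand)].

    Coordinates are 1-based inclusive; features are grouped by the Parent
    (falling back to ID) attribute and sorted along the transcript.
    """
    genes: dict[str, list[tuple[str, int, int, str]]] = {}
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "CDS":
                continue
            chrom, start, end, strand = cols[0], int(cols[3]), int(cols[4]), cols[6]
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gid = attrs.get("Parent", attrs.get("ID", "gene"))
            genes.setdefault(gid, []).append((chrom, start, end, strand))
    for gid, feats in genes.items():
        reverse = feats[0][3] == "-"
        feats.sort(key=lambda f: f[1], reverse=reverse)
    return genes


def _cds_position_map(genes, reference):
    """Map (chrom, genomic 1-based pos) -> (gene, cds_seq, cds_index, strand)."""
    pos_map = {}
    cds_seqs = {}
    for gid, feats in genes.items():
        strand = feats[0][3]
        parts, positions = [], []
        for chrom, start, end, _ in feats:
            seg = str(reference[chrom][start - 1:end]).upper()
            seg_positions = list(range(start, end + 1))
            if strand == "-":
                seg = reverse_complement(seg)
                seg_positions = seg_positions[::-1]
            parts.append(seg)
            positions.extend((chrom, p) for p in seg_positions)
        cds = "".join(parts)
        cds_seqs[gid] = cds
        for idx, key in enumerate(positions):
            pos_map[key] = (gid, idx, strand)
    return pos_map, cds_seqs


def read_outgroup_table(path) -> dict[tuple[str, int], tuple[str | None, str | None]]:
    """TSV (chrom, pos, outgroup1 base, outgroup2 base) -> lookup dict."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, b1, b2 = line.rstrip("\n").split("\t")[:4]
            out[(chrom, int(pos))] = (
                b1 if b1 in "ACGT" else None,
                b2 if b2 in "ACGT" else None,
            )
    return out


def extract_polarized_sites(
    vcf_path,
    fasta_path,
    gff_path,
    outgroup_path,
    n: int = 20,
    seed: int = 0,
    relaxed: bool = True,
    code: GeneticCode | None = None,
) -> tuple[list[PolarizedSite], dict, dict]:
    """Polarized coding SNPs from VCF + reference FASTA + GFF3 + outgroup TSV.

    Sites with more than n called chromosomes are hypergeometrically
    down-sampled to n (seeded); sites with fewer are dropped.  Returns
    (sites, monomorphic class counts from the reference CDS, tally of
    exclusion reasons).
    """
    import pysam
    from pyfaidx import Fasta

    code = code or standard_code()
    rng = np.random.default_rng(seed)
    reference = Fasta(str(fasta_path))
    genes = _read_gff_cds(gff_path)
    pos_map, cds_seqs = _cds_position_map(genes, reference)
    outgroups = read_outgroup_table(outgroup_path)
    mono = monomorphic_class_counts(list(cds_seqs.values()), code)

    sites: list[PolarizedSite] = []
    excluded = {"noncoding": 0, "not_biallelic_snp": 0, "low_coverage": 0,
                "unpolarized": 0, "monomorphic_after_projection": 0,
                "codon_unusable": 0}
    vcf = pysam.VariantFile(str(vcf_path))
    for rec in vcf:
        key = (rec.chrom, rec.pos)
        if key not in pos_map:
            excluded["noncoding"] += 1
            continue
        if len(rec.alleles) != 2 or any(len(a) != 1 for a in rec.alleles):
            excluded["not_biallelic_snp"] += 1
            continue
        ref_a, alt_a = rec.alleles
        calls = []
        for sample in rec.samples.values():
            for allele_idx in sample["GT"]:
                if allele_idx is not None:
                    calls.append(allele_idx)
        if len(calls) < n:
            excluded["low_coverage"] += 1
            continue
        if len(calls) > n:  # hypergeometric projection to common n
            alt_count = int(rng.hypergeometric(sum(calls), len(calls) - sum(calls), n))
        else:
            alt_count = sum(calls)
        if alt_count in (0, n):
            excluded["monomorphic_after_projection"] += 1
            continue
        counts = {ref_a: n - alt_count, alt_a: alt_count}
        og1, og2 = outgroups.get(key, (None, None))
        pol = polarize(counts, og1, og2, relaxed=relaxed)
        if pol is None:
            excluded["unpolarized"] += 1
            continue
        anc, der, i = pol
        gid, cds_idx, strand = pos_map[key]
        cds = cds_seqs[gid]
        codon_idx, within = divmod(cds_idx, 3)
        codon = cds[3 * codon_idx:3 * codon_idx + 3]
        if strand == "-":  # bases are stored genome-strand in the VCF
            anc_c, der_c = reverse_complement(anc), reverse_complement(der)
        else:
            anc_c, der_c = anc, der
        if len(codon) != 3 or not code.is_sense(codon[:within] + anc_c + codon[within + 1:]):
            excluded["codon_unusable"] += 1
            continue
        deg, mclass = classify_site(codon, within + 1, anc_c, der_c, code)
        sites.append(
            PolarizedSite(
                site_id=f"{rec.chrom}:{rec.pos}",
                codon=codon[:within] + anc_c + codon[within + 1:],
                codon_position=within + 1,
                degeneracy=deg,
                ancestral=anc_c,
                derived=der_c,
                derived_count=i,
                n=n,
                mutation_class=mclass,
            )
        )
    return sites, mono, excluded
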