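"""Summary statistics, regression models, and pipeline orchestration.

Thin layer over scipy.stats / statsmodels: rank correlations between
per-gene quantities (GC3 vs ω, ENC_diff vs dS, ...), nonparametric group
comparisons, the standardized log-ω multiple regression, and
``run_pipeline``, which exercises every stage on a synthetic bundle and
writes TSV/JSON artifacts with provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import __version__
from .popgen import bootstrap_fit
from .qc import reports_to_rows, run_qc
from .rates import CELLS, aggregate_tallies, branch_rates, sw_ratio
from .simulate import (
    AlignmentSimConfig,
    PopgenSimConfig,
    QCBatchConfig,
    TRNASimConfig,
    simulate_alignment,
    simulate_polymorphism,
    simulate_qc_batch,
    simulate_trnascan_fixture,
)
from .trna import copy_numbers, filter_functional, gc3_of_codon_equivalents, parse_trnascan
from .usage import enc_record


@dataclass(frozen=True)
class Association:
    """One rank-correlation row of an association table."""

    lineage: str
    x: str
    y: str
    rho: float
    p_value: float
    n: int


def compute_associations(df: pd.DataFrame, pairs, lineage_col: str = "lineage") -> pd.DataFrame:
    """Spearman rank correlations (midrank ties) per lineage and variable pair.

    ``pairs`` is an iterable of (x, y) column names.  Pairs with fewer
    than 3 complete observations or a constant variable yield NaN ρ
    (flagged, not dropped silently).
    """
    rows = []
    groups = df.groupby(lineage_col) if lineage_col in df.columns else [("all", df)]
    for lineage, sub in groups:
        for x, y in pairs:
            d = sub[[x, y]].dropna()
            if len(d) < 3 or d[x].nunique() < 2 or d[y].nunique() < 2:
                rows.append(Association(str(lineage), x, y, np.nan, np.nan, len(d)))
                continue
            rho, p = stats.spearmanr(d[x], d[y])
            rows.append(Association(str(lineage), x, y, float(rho), float(p), len(d)))
    return pd.DataFrame(rows)


def paired_signed_rank(a, b):
    """Wilcoxon signed-rank test for paired samples (two-sided)."""
    return stats.wilcoxon(a, b, alternative="two-sided")


def rank_sum(a, b):
    """Wilcoxon rank-sum (Mann-Whitney U) test (two-sided)."""
    return stats.mannwhitneyu(a, b, alternative="two-sided")


def kruskal(*groups):
    return stats.kruskal(*groups)


@dataclass
class RateModelFit:
    """Standardized OLS of log ω on GC3, ENC_obs and ENC_diff."""

    lineage: str
    coefficients: dict
    f_statistic: float
    f_pvalue: float
    adj_r_squared: float
    n: int
    condition_number: float


def fit_rate_model(
    df: pd.DataFrame,
    response: str = "omega",
    predictors: tuple[str, ...] = ("gc3", "enc_observed", "enc_difference"),
    lineage: str = "all",
) -> RateModelFit:
    """OLS of log(ω) on centered/scaled predictors.

    Rows with ω ≤ 0 or missing values are dropped (the log transform
    requires positive rates).  Predictors are standardized to mean 0,
    sd 1, so coefficients are comparable across scales; a condition
    number above 30 flags collinearity via a warning in the result.
    """
    d = df[[response, *predictors]].dropna()
    d = d[d[response] > 0]
    y = np.log(d[response].to_numpy())
    X = d[list(predictors)].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    model = sm.OLS(y, sm.add_constant(X)).fit()
    coefs = {"intercept": float(model.params[0])}
    coefs.update({p: float(model.params[i + 1]) for i, p in enumerate(predictors)})
    return RateModelFit(
        lineage=lineage,
        coefficients=coefs,
        f_statistic=float(model.fvalue),
        f_pvalue=float(model.f_pvalue),
        adj_r_squared=float(model.rsquared_adj),
        n=int(model.nobs),
        condition_number=float(np.linalg.cond(sm.add_constant(X))),
    )


def conserved_bin_comparison(df: pd.DataFrame, value_col: str, omega_col: str = "omega",
                             n_conserved: int = 100):
    """Compare a statistic between the lowest-ω genes and the rest.

    Returns the rank-sum test result plus group medians — the
    conserved-bin contrast (most conserved genes vs the remainder).
    """
    d = df[[omega_col, value_col]].dropna().sort_values(omega_col)
    conserved = d.head(n_conserved)[value_col]
    rest = d.iloc[n_conserved:][value_col]
    res = rank_sum(conserved, rest)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_conserved": float(conserved.median()),
        "median_rest": float(rest.median()),
        "n_conserved": len(conserved),
        "n_rest": len(rest),
    }


@dataclass
class PipelineConfig:
    """End-to-end synthetic run configuration."""

    seed: int = 0
    alignment: AlignmentSimConfig = None
    qc_batch: QCBatchConfig = None
    popgen: PopgenSimConfig = None
    trna: TRNASimConfig = None
    n_genes: int = 20
    n_bootstrap: int = 100

    def __post_init__(self):
        self.alignment = self.alignment or AlignmentSimConfig(n_genes=self.n_genes)
        self.qc_batch = self.qc_batch or QCBatchConfig()
        self.popgen = self.popgen or PopgenSimConfig(L_W=2e4, L_S=1.6e4)
        self.trna = self.trna or TRNASimConfig(outlier=("GGT", 57))


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run QC → usage → rates → popgen → tRNA → reports on synthetic data.

    Every artifact is written under ``outdir`` with a provenance JSON
    (seed, stage configs, package version, caveats).  Returns the bundle
    summary dict.  Identical config + seed reproduce identical artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    bundle: dict = {"stages": {}}

    # --- QC on a planted batch -------------------------------------------
    batch, qc_truth = simulate_qc_batch(config.qc_batch, rng)
    kept, reports = run_qc(batch)
    pd.DataFrame(reports_to_rows(reports)).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    bundle["stages"]["qc"] = {
        "n_input": len(batch),
        "n_kept": len(kept),
        "rejected": sorted(set(qc_truth) - {a.gene_id for a in kept}),
    }

    # --- Simulated alignments: usage + rates -----------------------------
    enc_rows, tally_rows, gene_tallies = [], [], {}
    for g in range(config.alignment.n_genes):
        aln, truth, tree = simulate_alignment(config.alignment, rng, gene_id=f"gene{g:03d}")
        for lid, seq in aln.sequences.items():
            rec = enc_record(aln.gene_id, lid, seq)
            if rec is not None:
                enc_rows.append(rec.__dict__)
        tallies = branch_rates(tree, aln, seed=config.seed)
        gene_tallies[aln.gene_id] = tallies
        for branch_id, tal in tallies.items():
            tally_rows.append({
                "gene": aln.gene_id, "branch": branch_id,
                "dn": tal.dn, "ds": tal.ds, "omega": tal.omega,
                **{f"N_{e}_{d}": tal.counts[i] for i, (e, d) in enumerate(CELLS)},
            })
    enc_df = pd.DataFrame(enc_rows)
    enc_df.to_csv(outdir / "enc_table.tsv", sep="\t", index=False)
    pd.DataFrame(tally_rows).to_csv(outdir / "branch_rates.tsv", sep="\t", index=False)

    per_branch = {}
    for tallies in gene_tallies.values():
        for branch_id, tal in tallies.items():
            per_branch.setdefault(branch_id, []).append(tal)
    branch_summary = {
        b: aggregate_tallies(ts, branch_id=b) for b, ts in per_branch.items()
    }
    ratios = sw_ratio(branch_summary.values())
    bundle["stages"]["rates"] = {
        "n_genes": len(gene_tallies),
        "sw_ratio_median": ratios["median"],
        "sw_ratio_mean": ratios["mean"],
    }

    # Associations on the per-gene-per-lineage ENC table.
    if not enc_df.empty:
        assoc = compute_associations(
            enc_df.rename(columns={"lineage_id": "lineage"}),
            [("gc3", "enc_observed"), ("gc3", "enc_difference")],
        )
        assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)

    # --- Popgen: simulate spectra and fit ---------------------------------
    pg_seed = int(rng.integers(2 ** 31))
    spectra, _ = simulate_polymorphism(config.popgen, np.random.default_rng(pg_seed))
    fit = bootstrap_fit(
        spectra["WS"], spectra["SW"], spectra["conservative"],
        config.popgen.L_W, config.popgen.L_S,
        n_boot=config.n_bootstrap, seed=pg_seed,
    )
    fit_payload = {
        "B": fit.B, "lambda": fit.lam,
        "theta_WS": fit.theta_WS, "theta_SW": fit.theta_SW,
        "theta_cons": fit.theta_cons, "loglik": fit.loglik,
        "converged": fit.converged,
        "B_ci": fit.bootstrap["B_ci"], "lambda_ci": fit.bootstrap["lambda_ci"],
        "n_boot": fit.bootstrap["n_boot"], "seed": pg_seed,
        "generating": {"B": config.popgen.B, "lambda": config.popgen.lam},
    }
    (outdir / "gbgc_fit.json").write_text(json.dumps(fit_payload, indent=2))
    bundle["stages"]["popgen"] = fit_payload

    # --- tRNA repertoire ---------------------------------------------------
    text, trna_truth = simulate_trnascan_fixture(config.trna, rng)
    trna_path = outdir / "trnascan.txt"
    trna_path.write_text(text)
    genes, _ = parse_trnascan(trna_path)
    functional = filter_functional(genes)
    summary = copy_numbers(functional)
    outlier_acs = set(summary.outliers())
    bundle["stages"]["trna"] = {
        "total_functional": summary.total_genes,
        "unique_anticodons": summary.unique_anticodons,
        "copy_number": summary.copy_number_summary(),
        "gc3_weighted": gc3_of_codon_equivalents(summary),
        "gc3_weighted_no_outlier": gc3_of_codon_equivalents(
            summary, exclude_anticodons=outlier_acs
        ) if outlier_acs else None,
        "planted": trna_truth["functional_copies"],
    }

    provenance = {
        "package": "lepcodon",
        "version": __version__,
        "seed": config.seed,
        "caveats": [
            "substitution rates use parsimony counting with fractional-site "
            "normalization, not probabilistic mapping; absolute scales are "
            "not comparable with codon-model mappers",
            "tRNA codon equivalents ignore wobble pairing",
        ],
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    bundle["provenance"] = provenance
    (outdir / "bundle.json").write_text(json.dumps(bundle, indent=2, default=str))
    return bundle
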