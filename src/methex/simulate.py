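"""Synthetic multi-omic HCC cohorts with planted ground truth.

The generator emulates the statistical structure the pipeline consumes,
without any download: a latent per-sample exhaustion level ``e_j`` drives
signature-gene expression and the death hazard; a latent salvage level
``s_j`` (positively coupled to ``e_j``) drives the salvage gene program while
an anti-correlated driver shapes the de novo program; planted metabolite
tumor/non-tumor ratios track ``e_j`` at a configured Spearman level through a
Gaussian copula; serum MTA tracks tumor salvage status; and the single-cell
bundle mixes salvage-high / de-novo-high malignant programs per tumor with
matched T cells whose exhaustion genes are elevated in salvage-dominant
tumors.

Expression is generated directly on the log2 scale (no count model): every
downstream operation acts on normalised log intensities. Censoring is
administrative — a single follow-up cutoff at the empirical survival quantile
matching ``censor_rate`` — which is independent of the event process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import ConfigurationError
from .genes import (
    CD3_GENES,
    CYTOLYTIC_GENES,
    DENOVO_GENES,
    DNMT_GENES,
    METHIONINE_GENES,
    PUBLISHED_FEATURES,
    SALVAGE_GENES,
)

__all__ = [
    "CohortConfig",
    "PlantedTruth",
    "SyntheticBundle",
    "generate_bulk_cohort",
    "generate_single_cell",
]

# fixed aspects of the stated world (documented in docs/methods.md)
_BASE_SIGNATURE = 7.0
_BASE_CD3 = 6.0
_BASE_CYTOLYTIC = 6.0
_BASE_PATHWAY = 8.0
_BASE_NOISE_GENE = 7.0
_PATHWAY_EFFECT = 1.0          # log2 units per SD of the latent pathway driver
_EXHAUSTION_SALVAGE_CORR = 0.5  # coupling of latent exhaustion and salvage levels
_BASELINE_HAZARD = 0.15
_NULL_MISSING_RATE = 0.05      # MAR missingness, null metabolites only
_SERUM_SALVAGE_COEF = 0.7
_SERUM_NOISE_SD = 0.5
_CNV_SLOPE = 0.4
_CNV_NOISE_SD = 0.25

# single-cell defaults mirroring the four-patient compartment sizes
_SC_TUMOR_FRACTIONS = (0.9, 0.8, 0.7, 0.2)
_SC_CELLS_PER_TUMOR = 130
_SC_T_CELLS = (52, 51, 51, 21)


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic world; defaults are the stated conditions."""

    n_samples: int = 100
    n_signature_genes: int = 82
    n_noise_genes: int = 100
    exhaustion_effect: float = 1.0
    hazard_log_hr: float = 1.0
    censor_rate: float = 0.3
    metabolite_rho: float = 0.444
    n_null_metabolites: int = 200
    salvage_denovo_anticorr: float = -0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        checks = [
            ("n_samples", self.n_samples >= 4, "must be >= 4"),
            ("n_signature_genes", self.n_signature_genes >= 4, "must be >= 4"),
            ("n_noise_genes", self.n_noise_genes >= 0, "must be >= 0"),
            ("censor_rate", 0.0 <= self.censor_rate <= 1.0, "must be in [0, 1]"),
            ("metabolite_rho", -1.0 < self.metabolite_rho < 1.0, "must be in (-1, 1)"),
            ("n_null_metabolites", self.n_null_metabolites >= 0, "must be >= 0"),
            (
                "salvage_denovo_anticorr",
                -1.0 <= self.salvage_denovo_anticorr <= 0.0,
                "must be in [-1, 0]",
            ),
            ("noise_sd", self.noise_sd > 0, "must be > 0"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ConfigurationError(f"invalid CohortConfig field '{name}': {msg} "
                                         f"(got {getattr(self, name)!r})")


@dataclass
class PlantedTruth:
    latent_exhaustion: pd.Series
    latent_salvage: pd.Series
    informative_metabolites: list[str]
    true_log_hr: float


@dataclass
class SyntheticBundle:
    """Everything one cohort provides, with its planted truth attached."""

    bulk_expression: pd.DataFrame
    clinical: pd.DataFrame
    tumor_metabolome: pd.DataFrame
    nontumor_metabolome: pd.DataFrame
    serum_metabolome: pd.DataFrame
    single_cell: ad.AnnData
    cnv: pd.DataFrame
    truth: PlantedTruth
    signature_genes: list[str] = field(default_factory=list)
    config: CohortConfig | None = None

    def write(self, out_dir) -> dict[str, Path]:
        from .io import (
            write_expression,
            write_metabolites,
            write_single_cell,
            write_survival,
            write_table,
        )

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["expression"] = out_dir / "expression.tsv"
        write_expression(self.bulk_expression, paths["expression"])
        paths["clinical"] = out_dir / "clinical.tsv"
        write_survival(self.clinical, paths["clinical"])
        for name, table in (
            ("tumor_metabolome", self.tumor_metabolome),
            ("nontumor_metabolome", self.nontumor_metabolome),
            ("serum_metabolome", self.serum_metabolome),
        ):
            paths[name] = out_dir / f"{name}.tsv"
            write_metabolites(table, paths[name])
        paths["cnv"] = out_dir / "cnv.tsv"
        write_expression(self.cnv, paths["cnv"])
        sig = pd.DataFrame({"gene": self.signature_genes, "weight_eligible": 1})
        paths["signature"] = out_dir / "signature.tsv"
        write_table(sig, paths["signature"], index=False)
        truth = pd.DataFrame(
            {
                "latent_exhaustion": self.truth.latent_exhaustion,
                "latent_salvage": self.truth.latent_salvage,
            }
        )
        paths["truth"] = out_dir / "truth.tsv"
        write_table(truth, paths["truth"], index_label="sample")
        paths.update(write_single_cell(self.single_cell, out_dir / "single_cell"))
        return paths


def _signature_gene_names(n: int) -> list[str]:
    names = list(PUBLISHED_FEATURES)
    names += [f"SIG{i:04d}" for i in range(len(names) + 1, n + 1)]
    return names[:n]


def generate_bulk_cohort(config: CohortConfig) -> SyntheticBundle:
    """Generate the full multi-omic bundle for one cohort.

    Deterministic given ``config`` (the seed feeds a SeedSequence tree). See
    the module docstring for the planted structure.
    """
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rngs = [np.random.default_rng(s) for s in streams]
    r_latent, r_expr, r_surv, r_metab, r_serum, r_cnv, _r_sc, r_noise = rngs

    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(1, n + 1)]

    e = r_latent.standard_normal(n)
    rho_es = _EXHAUSTION_SALVAGE_CORR
    s = rho_es * e + np.sqrt(1 - rho_es**2) * r_latent.standard_normal(n)
    a = config.salvage_denovo_anticorr
    d = a * s + np.sqrt(1 - a**2) * r_latent.standard_normal(n)

    sig_genes = _signature_gene_names(config.n_signature_genes)
    noise_genes = [f"NOISE{i:04d}" for i in range(1, config.n_noise_genes + 1)]

    blocks = {}
    sd = config.noise_sd
    for g in sig_genes:
        blocks[g] = _BASE_SIGNATURE + config.exhaustion_effect * e + sd * r_expr.standard_normal(n)
    for g in CD3_GENES:
        blocks[g] = _BASE_CD3 + sd * r_expr.standard_normal(n)
    for g in CYTOLYTIC_GENES:
        blocks[g] = _BASE_CYTOLYTIC - config.exhaustion_effect * e + sd * r_expr.standard_normal(n)
    for g in SALVAGE_GENES:
        blocks[g] = _BASE_PATHWAY + _PATHWAY_EFFECT * s + sd * r_expr.standard_normal(n)
    for g in DENOVO_GENES:
        blocks[g] = _BASE_PATHWAY + _PATHWAY_EFFECT * d + sd * r_expr.standard_normal(n)
    for g in noise_genes:
        blocks[g] = _BASE_NOISE_GENE + sd * r_noise.standard_normal(n)
    expr = pd.DataFrame(blocks, index=samples).T
    expr.index.name = "gene"

    # survival: exponential with hazard prop. to exp(gamma * e), single
    # administrative cutoff at the empirical quantile matching censor_rate
    hazard = _BASELINE_HAZARD * np.exp(config.hazard_log_hr * e)
    t_event = r_surv.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        cutoff = np.quantile(t_event, 1.0 - config.censor_rate)
    else:
        cutoff = np.inf
    time = np.minimum(t_event, cutoff)
    event = (t_event <= cutoff).astype(int)
    clinical = pd.DataFrame({"time": time, "event": event}, index=samples)
    clinical.index.name = "sample"

    # metabolome: planted MTA/SAM T/N log-ratios at the target Spearman level
    # via the Gaussian copula (rho_pearson = 2 sin(pi rho_s / 6))
    informative = ["MTA", "SAM"]
    rho_p = 2.0 * np.sin(np.pi * config.metabolite_rho / 6.0)
    nulls = [f"MET{i:04d}" for i in range(1, config.n_null_metabolites + 1)]
    nontumor_log = pd.DataFrame(
        10.0 + r_metab.standard_normal((len(informative) + len(nulls), n)),
        index=informative + nulls,
        columns=samples,
    )
    logratio = pd.DataFrame(
        r_metab.standard_normal((len(nulls), n)), index=nulls, columns=samples
    )
    for met in informative:
        z = rho_p * e + np.sqrt(1 - rho_p**2) * r_metab.standard_normal(n)
        logratio.loc[met] = z
    logratio = logratio.loc[informative + nulls]
    tumor_log = nontumor_log + logratio
    tumor = np.power(2.0, tumor_log)
    nontumor = np.power(2.0, nontumor_log)
    for table in (tumor, nontumor):  # MAR missingness in null metabolites only
        mask = r_metab.random((len(nulls), n)) < _NULL_MISSING_RATE
        block = table.loc[nulls].to_numpy()
        block[mask] = np.nan
        table.loc[nulls] = block
    tumor.index.name = nontumor.index.name = "metabolite"

    # serum: MTA tracks tumor salvage status after methionine normalisation
    methionine = np.power(2.0, 12.0 + 0.5 * r_serum.standard_normal(n))
    serum_mta = methionine * np.power(
        2.0, _SERUM_SALVAGE_COEF * s + _SERUM_NOISE_SD * r_serum.standard_normal(n)
    )
    serum_nulls = [f"SER{i:04d}" for i in range(1, 21)]
    serum = pd.DataFrame(
        np.power(2.0, 10.0 + r_serum.standard_normal((len(serum_nulls), n))),
        index=serum_nulls,
        columns=samples,
    )
    serum.loc["MTA"] = serum_mta
    serum.loc["methionine"] = methionine
    serum = serum.loc[["MTA", "methionine"] + serum_nulls]
    serum.index.name = "metabolite"

    # per-gene copy-number summary values tracking expression
    cnv_rows = {}
    for g in METHIONINE_GENES:
        x = expr.loc[g].to_numpy()
        z = (x - x.mean()) / x.std()
        cnv_rows[g] = _CNV_SLOPE * z + _CNV_NOISE_SD * r_cnv.standard_normal(n)
    cnv = pd.DataFrame(cnv_rows, index=samples).T
    cnv.index.name = "gene"

    single_cell = generate_single_cell(
        config,
        n_tumors=len(_SC_TUMOR_FRACTIONS),
        cells_per_tumor=_SC_CELLS_PER_TUMOR,
        salvage_fraction_per_tumor=_SC_TUMOR_FRACTIONS,
        t_cells_per_tumor=_SC_T_CELLS,
    )

    truth = PlantedTruth(
        latent_exhaustion=pd.Series(e, index=samples, name="latent_exhaustion"),
        latent_salvage=pd.Series(s, index=samples, name="latent_salvage"),
        informative_metabolites=informative,
        true_log_hr=config.hazard_log_hr,
    )
    return SyntheticBundle(
        bulk_expression=expr,
        clinical=clinical,
        tumor_metabolome=tumor,
        nontumor_metabolome=nontumor,
        serum_metabolome=serum,
        single_cell=single_cell,
        cnv=cnv,
        truth=truth,
        signature_genes=sig_genes,
        config=config,
    )


def generate_single_cell(
    config: CohortConfig,
    n_tumors: int = 4,
    cells_per_tumor: int = _SC_CELLS_PER_TUMOR,
    salvage_fraction_per_tumor=_SC_TUMOR_FRACTIONS,
    t_cells_per_tumor=50,
    program_shift: float | None = None,
    exhaustion_shift: float = 1.0,
) -> ad.AnnData:
    """Simulate malignant cells from two metabolic programs plus matched T cells.

    Each tumor mixes salvage-high and de-novo-high malignant cells at its
    configured fraction; the per-pathway-gene mean shift between the two
    programs defaults to ``2 * noise_sd``. T cells of tumors whose salvage
    fraction exceeds 0.5 have their exhaustion-signature genes raised by
    ``exhaustion_shift`` (and DNA methyltransferases by half of it).

    Cell metadata records cell_type (malignant/T), tumor of origin and, for
    malignant cells, the true program label.
    """
    fractions = np.atleast_1d(np.asarray(salvage_fraction_per_tumor, dtype=float))
    if fractions.size == 1:
        fractions = np.repeat(fractions, n_tumors)
    if fractions.size != n_tumors:
        raise ConfigurationError(
            f"salvage_fraction_per_tumor length {fractions.size} != n_tumors {n_tumors}"
        )
    if ((fractions < 0) | (fractions > 1)).any():
        raise ConfigurationError("invalid field 'salvage_fraction_per_tumor': fractions must be in [0, 1]")
    if cells_per_tumor < 2:
        raise ConfigurationError("invalid field 'cells_per_tumor': must be >= 2")
    t_counts = np.atleast_1d(np.asarray(t_cells_per_tumor, dtype=int))
    if t_counts.size == 1:
        t_counts = np.repeat(t_counts, n_tumors)
    if t_counts.size != n_tumors:
        raise ConfigurationError("t_cells_per_tumor must be scalar or length n_tumors")

    shift = 2.0 * config.noise_sd if program_shift is None else float(program_shift)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[6])

    sig_genes = _signature_gene_names(config.n_signature_genes)
    noise_genes = [f"NOISE{i:04d}" for i in range(1, min(config.n_noise_genes, 50) + 1)]
    genes = (
        list(METHIONINE_GENES)
        + sig_genes
        + list(CD3_GENES)
        + list(DNMT_GENES)
        + list(CYTOLYTIC_GENES)
        + noise_genes
    )
    gi = {g: i for i, g in enumerate(genes)}
    salv_idx = [gi[g] for g in SALVAGE_GENES]
    deno_idx = [gi[g] for g in DENOVO_GENES]
    sig_idx = [gi[g] for g in sig_genes]
    cd3_idx = [gi[g] for g in CD3_GENES]
    dnmt_idx = [gi[g] for g in DNMT_GENES]

    base_malignant = 1.5
    base_other = 1.0

    rows = []
    obs_rows = []
    cell_no = 0
    for t in range(n_tumors):
        tumor_id = f"T{t + 1}"
        n_salv = int(round(fractions[t] * cells_per_tumor))
        programs = ["salvage-high"] * n_salv + ["de novo-high"] * (cells_per_tumor - n_salv)
        for prog in programs:
            cell_no += 1
            mu = np.full(len(genes), base_other)
            mu[salv_idx] = base_malignant + (shift if prog == "salvage-high" else 0.0)
            mu[deno_idx] = base_malignant + (shift if prog == "de novo-high" else 0.0)
            rows.append(mu + config.noise_sd * rng.standard_normal(len(genes)))
            obs_rows.append(
                {"cell_id": f"C{cell_no:05d}", "cell_type": "malignant",
                 "tumor": tumor_id, "true_program": prog}
            )
        salvage_dominant = fractions[t] > 0.5
        for _ in range(t_counts[t]):
            cell_no += 1
            mu = np.full(len(genes), base_other)
            mu[cd3_idx] = 3.0
            mu[sig_idx] = base_other + (exhaustion_shift if salvage_dominant else 0.0)
            mu[dnmt_idx] = base_other + (0.5 * exhaustion_shift if salvage_dominant else 0.0)
            rows.append(mu + config.noise_sd * rng.standard_normal(len(genes)))
            obs_rows.append(
                {"cell_id": f"C{cell_no:05d}", "cell_type": "T",
                 "tumor": tumor_id, "true_program": ""}
            )

    X = np.clip(np.asarray(rows), 0.0, None)
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    return ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)
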