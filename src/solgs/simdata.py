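"""Synthetic genotypes and phenotypes emulating a cultivated/wild panel.

Genotypes: a large cultivated group plus several small, divergent wild
species groups.  Group allele frequencies follow the Balding-Nichols
construction (Beta-distributed around a shared ancestral frequency with
dispersion set by an F_ST-like parameter); the cultivated group uses the
ancestral frequencies directly.  Within a group, haplotypes are drawn from a
latent stationary AR(1) Gaussian process per chromosome thresholded at the
group allele-frequency quantile, which produces linkage disequilibrium that
decays with marker distance; two haplotypes are summed to a 0/1/2 dosage.

Two choices make the LD realistic on the dosage scale.  First, thresholding
attenuates correlation, so the latent AR(1) coefficient is calibrated
(arcsine relation at balanced frequency) such that ``ld_rho`` is the target
squared correlation (r2) of adjacent common SNPs, the scale tag-SNP
selection operates on.  Second, ancestral frequencies vary smoothly along
each chromosome (a thresholded copy of the same latent process): markers in
strong LD necessarily have similar allele frequencies, as in real data,
otherwise the binary max-correlation bound would cap attainable r2 far
below one.

Phenotypes: polygenic traits with a controlled narrow-sense heritability and
a trial/replicate observation structure, y_ijk = mu + g_i + t_j + e_ijk.
Drawn trial-effect and residual vectors are rescaled to their exact target
variances so the realized variance partition matches the requested one; the
genetic score is likewise standardized before scaling by sqrt(h2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .genotypes import MISSING, GenotypeMatrix

#: Wild species group sizes for the default tomato-like panel: seven small
#: divergent species groups totalling 34 accessions beside 146 cultivated
#: ones.  Per-species counts of the complete-data wild subset are not known
#: individually; sizes avoid singletons so every species keeps at least one
#: member in held-out sets under stratified transfer scenarios.
DEFAULT_WILD_SIZES = (8, 6, 5, 4, 4, 4, 3)


@dataclass
class PopulationSpec:
    """Parameters of the simulated cultivated + wild population."""

    n_cultivated: int = 146
    wild_group_sizes: tuple = DEFAULT_WILD_SIZES
    n_snps: int = 10_000
    n_chromosomes: int = 12
    ld_rho: float = 0.9          # target adjacent-SNP dosage r2 (common SNPs)
    fst_wild: float = 0.3        # Balding-Nichols differentiation of wild groups
    ld_phase_divergence: float = 0.5  # per-site chance a wild group couples
    #   to its latent LD chain with flipped sign (diverged species share
    #   allele frequencies but not local haplotype phase)
    maf_floor: float = 0.01      # minimum simulated allele frequency
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cultivated <= 0 or self.n_snps <= 0 or self.n_chromosomes <= 0:
            raise ValueError("counts must be positive")
        if any(s <= 0 for s in self.wild_group_sizes):
            raise ValueError("wild group sizes must be positive")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 < self.fst_wild < 1:
            raise ValueError("fst_wild must be in (0, 1)")
        if not 0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in (0, 0.5)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.ld_phase_divergence <= 1:
            raise ValueError("ld_phase_divergence must be in [0, 1]")


@dataclass
class TraitSpec:
    """Parameters of a simulated polygenic trait with trial structure.

    ``h2`` is the single-observation narrow-sense heritability target;
    ``trial_var_frac`` splits the non-genetic variance between trial effects
    and residuals.  ``genetic_corr`` (t x t, unit diagonal, PSD) requests
    correlated effect vectors for multi-trait simulation.
    """

    n_qtl: int = 200
    h2: float = 0.5
    n_trials: int = 4            # tomato design; pepper used 3
    trial_var_frac: float = 0.3
    n_reps: int = 8
    mu: float = 0.0
    genetic_corr: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl <= 0 or self.n_trials <= 0 or self.n_reps <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must be in [0, 1]")
        if not 0 <= self.trial_var_frac <= 1:
            raise ValueError("trial_var_frac must be in [0, 1]")
        if self.genetic_corr is not None:
            C = np.asarray(self.genetic_corr, dtype=float)
            if C.ndim != 2 or C.shape[0] != C.shape[1]:
                raise ValueError("genetic_corr must be square")
            if not np.allclose(C, C.T):
                raise ValueError("genetic_corr must be symmetric")
            if not np.allclose(np.diag(C), 1.0):
                raise ValueError("genetic_corr must have unit diagonal")
            if np.min(np.linalg.eigvalsh(C)) < -1e-10:
                raise ValueError("genetic_corr must be positive semi-definite")
            self.genetic_corr = C


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _latent_coefficient(ld_rho: float) -> float:
    """Latent AR(1) coefficient yielding adjacent dosage r2 ~ ``ld_rho``.

    Uses the arcsine (tetrachoric) relation phi = (2/pi) arcsin(rho) at a
    balanced threshold, inverted at phi = sqrt(ld_rho); realized r2 is
    close to the target for common variants and lower toward the rare tail.
    """
    if ld_rho <= 0:
        return 0.0
    return min(float(np.sin(np.pi * np.sqrt(ld_rho) / 2.0)), 0.9999)


def _ar1_process(rng: np.random.Generator, n_rows: int, m: int,
                 rho: float) -> np.ndarray:
    """Rows of a stationary (marginally N(0,1)) AR(1) process of length m."""
    x = np.empty((n_rows, m))
    x[:, 0] = rng.standard_normal(n_rows)
    if m > 1:
        innov = rng.standard_normal((n_rows, m - 1)) * np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            x[:, j] = rho * x[:, j - 1] + innov[:, j - 1]
    return x


def _ar1_haplotypes(rng: np.random.Generator, n_hap: int, freqs: np.ndarray,
                    rho: float, phase: np.ndarray | None = None) -> np.ndarray:
    """Haplotype alleles from a thresholded latent AR(1) Gaussian process.

    An allele is 1 when the (possibly sign-flipped) latent value falls
    below the marginal quantile of its site frequency, so each site keeps
    the requested allele frequency while adjacent sites correlate through
    the latent chain.  ``phase`` (+/-1 per site) couples a site to the
    chain with flipped sign, reversing its local LD phase without touching
    its frequency.
    """
    x = _ar1_process(rng, n_hap, len(freqs), rho)
    if phase is not None:
        x = x * phase[None, :]
    return (x < norm.ppf(freqs)[None, :]).astype(np.int8)


def simulate_genotypes(spec: PopulationSpec) -> GenotypeMatrix:
    """Simulate the structured dosage matrix described by ``spec``.

    Deterministic under ``spec.seed``; SNPs are split as evenly as possible
    over chromosomes with increasing 1-based positions.
    """
    rng = np.random.default_rng(spec.seed)
    m, n_chr = spec.n_snps, spec.n_chromosomes
    chrom_sizes = np.full(n_chr, m // n_chr)
    chrom_sizes[: m % n_chr] += 1
    rho = _latent_coefficient(spec.ld_rho)

    # ancestral frequencies: smooth along each chromosome so that linked
    # markers have similar frequencies (uniform marginally, then clipped)
    z = np.concatenate([_ar1_process(rng, 1, sz, rho)[0] for sz in chrom_sizes])
    p0 = np.clip(norm.cdf(z), spec.maf_floor, 1.0 - spec.maf_floor)
    groups: list[tuple] = [
        ("cultivated", False, spec.n_cultivated, p0, None)
    ]
    F = spec.fst_wild
    for g, size in enumerate(spec.wild_group_sizes):
        a = p0 * (1.0 - F) / F
        b = (1.0 - p0) * (1.0 - F) / F
        # Balding-Nichols marginals driven by a smooth uniform so group
        # frequency deviations are coherent along the chromosome (site-
        # independent deviations would erase LD in the pooled panel)
        u = norm.cdf(np.concatenate(
            [_ar1_process(rng, 1, sz, rho)[0] for sz in chrom_sizes]))
        pg = np.clip(beta_dist.ppf(u, a, b), spec.maf_floor, 1.0 - spec.maf_floor)
        # diverged species: a random site subset couples to the latent
        # chain with flipped sign, reshuffling local haplotype phase
        phase = np.where(rng.random(m) < spec.ld_phase_divergence, -1.0, 1.0)
        groups.append((f"wild_{g + 1}", True, size, pg, phase))

    n_total = sum(g[2] for g in groups)
    dosage = np.empty((n_total, m), dtype=np.int8)
    species, is_wild, acc_ids = [], [], []
    row = 0
    for name, wild, size, freqs, phase in groups:
        start = 0
        for sz in chrom_sizes:
            ph = None if phase is None else phase[start : start + sz]
            hap = _ar1_haplotypes(rng, 2 * size, freqs[start : start + sz],
                                  rho, ph)
            dosage[row : row + size, start : start + sz] = hap[:size] + hap[size:]
            start += sz
        for i in range(size):
            acc_ids.append(f"{name}_{i + 1}")
            species.append("cultivated" if not wild else name)
            is_wild.append(wild)
        row += size

    if spec.missing_rate > 0:
        # GBS no-call rates are strongly SNP-dependent: a right-skewed Beta
        # with mean missing_rate leaves most SNPs nearly complete while a
        # small tail exceeds the 50%-missingness QC threshold
        alpha = 0.4
        beta_par = alpha * (1.0 - spec.missing_rate) / spec.missing_rate
        q = rng.beta(alpha, beta_par, size=dosage.shape[1])
        miss = rng.random(dosage.shape) < q[None, :]
        dosage[miss] = MISSING

    chrom = np.concatenate(
        [np.full(sz, f"chr{c + 1}", dtype=object) for c, sz in enumerate(chrom_sizes)]
    )
    pos = np.concatenate([np.arange(1, sz + 1) * 100 for sz in chrom_sizes])
    meta = pd.DataFrame(
        {"species": species, "is_wild": is_wild},
        index=pd.Index(acc_ids, name="accession"),
    )
    return GenotypeMatrix(
        accession_ids=np.asarray(acc_ids, dtype=object),
        variant_ids=np.asarray([f"snp_{j + 1}" for j in range(m)], dtype=object),
        chrom=chrom,
        pos=pos,
        dosage=dosage,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def _scaled_to_variance(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale ``x`` to exact population variance ``target_var``."""
    x = x - x.mean()
    v = x.var()
    if v == 0 or target_var == 0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


def _simulate_core(G: GenotypeMatrix, spec: TraitSpec, corr: np.ndarray,
                   trait_names: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    if not G.is_complete:
        raise ValueError("genotypes must be complete (impute first)")
    n, m = G.dosage.shape
    if spec.n_qtl > m:
        raise ValueError("n_qtl exceeds the number of SNPs")
    t = corr.shape[0]
    rng = np.random.default_rng(spec.seed)

    qtl = rng.choice(m, size=spec.n_qtl, replace=False)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(t))
    effects = rng.standard_normal((spec.n_qtl, t)) @ L.T
    Zq = G.dosage[:, qtl].astype(float)
    Zq -= Zq.mean(axis=0)
    scores = Zq @ effects  # n x t raw breeding values

    # standardize each trait's genetic score to unit variance, then scale by
    # sqrt(h2); at h2=0 the returned truth keeps the unit-variance latent
    # score (nonconstant) while the phenotype carries no genetic signal.
    records = []
    true_vals = np.empty((n, t))
    h2 = spec.h2
    var_t = spec.trial_var_frac * (1.0 - h2)
    var_e = (1.0 - spec.trial_var_frac) * (1.0 - h2)
    for a in range(t):
        s = _scaled_to_variance(scores[:, a], 1.0)
        g = np.sqrt(h2) * s
        true_vals[:, a] = g if h2 > 0 else s
        trial_eff = _scaled_to_variance(rng.standard_normal(spec.n_trials), var_t)
        resid = _scaled_to_variance(
            rng.standard_normal((n, spec.n_trials, spec.n_reps)).ravel(), var_e
        ).reshape(n, spec.n_trials, spec.n_reps)
        vals = spec.mu + g[:, None, None] + trial_eff[None, :, None] + resid
        for j in range(spec.n_trials):
            for k in range(spec.n_reps):
                records.append(
                    pd.DataFrame(
                        {
                            "accession": G.accession_ids,
                            "trial": f"trial_{j + 1}",
                            "replicate": k + 1,
                            "trait": trait_names[a],
                            "value": vals[:, j, k],
                        }
                    )
                )
    tbl = pd.concat(records, ignore_index=True)
    return tbl, true_vals


def simulate_trait(G: GenotypeMatrix, spec: TraitSpec,
                   trait_name: str = "trait") -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one polygenic trait with trial/replicate structure.

    Returns the long-format phenotype table (accession, trial, replicate,
    trait, value) and the per-accession true breeding values in the order of
    ``G.accession_ids``.
    """
    tbl, tv = _simulate_core(G, spec, np.eye(1), [trait_name])
    return tbl, tv[:, 0]


def simulate_multitrait(G: GenotypeMatrix, spec: TraitSpec,
                        trait_names: list[str] | None = None
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate correlated traits sharing causal loci.

    ``spec.genetic_corr`` (t x t) sets the correlation of the per-locus
    effect vectors; realized breeding-value correlations reproduce it up to
    sampling error.  With a 1x1 matrix this reduces exactly to
    :func:`simulate_trait` under the same seed.
    """
    if spec.genetic_corr is None:
        raise ValueError("simulate_multitrait requires genetic_corr")
    C = np.asarray(spec.genetic_corr, dtype=float)
    t = C.shape[0]
    if trait_names is None:
        trait_names = [f"trait_{a + 1}" for a in range(t)]
    return _simulate_core(G, spec, C, trait_names)


def derive_categorical_trait(values: np.ndarray, class_proportions) -> np.ndarray:
    """Assign ordinal class labels 0..K-1 by rank quantiles of ``values``.

    Class counts follow a floor/largest-remainder allocation of
    ``proportions * n``.  The map is monotone (a higher value never gets a
    lower class) and invariant to strictly increasing transforms; tied
    values all receive the lowest class occurring in the tie group, so a
    constant vector lands entirely in the first class.
    """
    values = np.asarray(values, dtype=float)
    props = np.asarray(class_proportions, dtype=float)
    if np.any(props <= 0) or not np.isclose(props.sum(), 1.0):
        raise ValueError("class proportions must be positive and sum to 1")
    n = len(values)
    counts = np.floor(props * n).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        frac = props * n - np.floor(props * n)
        for j in np.argsort(-frac, kind="stable")[:remainder]:
            counts[j] += 1
    order = np.argsort(values, kind="stable")  # ties -> accession order
    labels = np.empty(n, dtype=int)
    labels[order] = np.repeat(np.arange(len(props)), counts)
    # tied values share the lowest label in the tie group
    for v in np.unique(values):
        mask = values == v
        labels[mask] = labels[mask].min()
    return labels


def write_phenotypes(tbl: pd.DataFrame, path: str) -> None:
    tbl.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
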