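"""Mixed disomic/tetrasomic inheritance model for a duplex x nulliplex cross.

Model
-----
A doubled-diploid (duplex, AAMM) parent produces diploid gametes. With
probability ``PP`` (preferential pairing) meiosis pairs strictly homologous
chromosomes (M with M, A with A) and every gamete is AM. With probability
``tau = 1 - PP`` pairing is random among the four chromosomes: the three
bivalent configurations are equally likely, which gives the classical
1 AA : 4 AM : 1 MM duplex segregation in the absence of double reduction.
Double reduction (a gamete receiving two copies of the same original
chromosome region, requiring quadrivalent formation plus a crossover between
centromere and locus) occurs within the random-pairing fraction at relative
frequency ``beta`` (admissible maximum 1/6) and yields AA or MM with equal
probability. Hence

    p_AM = PP + tau * (2/3) * (1 - beta)
    p_AA = p_MM = tau * ((1 - beta)/6 + beta/2)

Closed-form maximum-likelihood estimators follow from the homozygote
fraction: at a centromeric locus (beta = 0) ``tau_hat = 3 * f_hom``; at a
telomeric locus with tau fixed, ``beta_hat = (3 * f_hom / tau - 1) / 2``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import MISSING, GameteMatrix

logger = logging.getLogger(__name__)

BETA_MAX = 1.0 / 6.0


class ModelError(ValueError):
    """Raised on out-of-range parameters or unusable counts."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed AA/AM/MM gamete counts at one locus."""

    n_AA: int
    n_AM: int
    n_MM: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_AM, self.n_MM) < 0:
            raise ModelError("negative genotype count")

    @property
    def n(self) -> int:
        return self.n_AA + self.n_AM + self.n_MM

    @property
    def f_hom(self) -> float:
        if self.n == 0:
            raise ModelError("no observed gametes")
        return (self.n_AA + self.n_MM) / self.n

    def as_array(self) -> np.ndarray:
        return np.array([self.n_AA, self.n_AM, self.n_MM], dtype=float)


@dataclass
class InheritanceEstimate:
    """Per-chromosome pairing and double-reduction estimates."""

    chromosome: str
    PP: float
    tau: float
    beta: float
    PP_sd: float
    beta_sd: float
    n_centromeric: int
    n_telomeric: int
    tau_per_marker: dict[str, float]
    beta_per_marker: dict[str, float]


@dataclass
class PhrSummary:
    """Parental-heterozygosity-restitution statistics."""

    per_marker: pd.DataFrame  # marker_id, chromosome, role, n_obs, phr
    per_gamete: pd.DataFrame  # gamete_id, n_obs, phr
    per_chromosome: pd.DataFrame  # chromosome, phr_mean, phr_sd, pct_full_* columns
    genome_mean: float


def counts_at(g: GameteMatrix, marker_idx: int) -> GenotypeCounts:
    """Tally observed gamete genotypes at one marker column."""
    col = g.genotype[:, marker_idx]
    return GenotypeCounts(
        n_AA=int((col == 0).sum()),
        n_AM=int((col == 1).sum()),
        n_MM=int((col == 2).sum()),
    )


def genotype_probs(PP: float, beta: float = 0.0) -> tuple[float, float, float]:
    """Gamete genotype probabilities (p_AA, p_AM, p_MM) at a duplex locus."""
    if not 0.0 <= PP <= 1.0:
        raise ModelError(f"PP={PP} outside [0, 1]")
    if not 0.0 <= beta <= BETA_MAX + 1e-12:
        raise ModelError(f"beta={beta} outside [0, 1/6]")
    tau = 1.0 - PP
    p_am = PP + tau * (2.0 / 3.0) * (1.0 - beta)
    p_hom = tau * ((1.0 - beta) / 6.0 + beta / 2.0)
    return (p_hom, p_am, p_hom)


def loglik(counts: GenotypeCounts, PP: float, beta: float = 0.0) -> float:
    """Multinomial log-likelihood of the observed counts (with coefficient).

    Returns -inf when a genotype class with observed counts has zero
    probability under (PP, beta).
    """
    probs = np.array(genotype_probs(PP, beta))
    ks = counts.as_array()
    if np.any((ks > 0) & (probs == 0.0)):
        return -math.inf
    coef = gammaln(counts.n + 1) - gammaln(ks + 1).sum()
    with np.errstate(divide="ignore"):
        logp = np.where(ks > 0, ks * np.log(np.where(probs > 0, probs, 1.0)), 0.0)
    return float(coef + logp.sum())


def estimate_tau(counts: GenotypeCounts) -> tuple[float, float]:
    """ML estimate of the tetrasomic rate at a centromeric locus (beta = 0).

    Closed form ``tau_hat = 3 * (n_AA + n_MM) / n`` clipped to [0, 1];
    standard error by the binomial delta method on the homozygote fraction.
    """
    if counts.n == 0:
        raise ModelError("cannot estimate tau from zero gametes")
    f = counts.f_hom
    tau_hat = 3.0 * f
    if tau_hat > 1.0:
        logger.warning("tau estimate %.4f clipped to 1", tau_hat)
        tau_hat = 1.0
    se = 3.0 * math.sqrt(f * (1.0 - f) / counts.n)
    return tau_hat, se


def estimate_dr(counts: GenotypeCounts, tau: float) -> tuple[float, float]:
    """ML estimate of double reduction at a telomeric locus, tau held fixed.

    Closed form ``beta_hat = (3*f_hom/tau - 1)/2`` clipped to [0, 1/6].
    """
    if counts.n == 0:
        raise ModelError("cannot estimate beta from zero gametes")
    if tau <= 0.0:
        raise ModelError("beta unidentifiable under full disomy (tau = 0)")
    f = counts.f_hom
    beta_hat = (3.0 * f / tau - 1.0) / 2.0
    if beta_hat < 0.0 or beta_hat > BETA_MAX:
        logger.info("beta estimate %.4f clipped to [0, 1/6]", beta_hat)
        beta_hat = min(max(beta_hat, 0.0), BETA_MAX)
    se = (3.0 / (2.0 * tau)) * math.sqrt(f * (1.0 - f) / counts.n)
    return beta_hat, se


def bootstrap_se(
    g: GameteMatrix,
    marker_idx: int,
    estimator: str = "tau",
    tau: float | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> float:
    """Bootstrap SE (resampling gametes) for tau_hat or beta_hat at a marker."""
    rng = np.random.default_rng(seed)
    col = g.genotype[:, marker_idx]
    col = col[col != MISSING]
    if col.size == 0:
        raise ModelError("no observed gametes at marker")
    estimates = np.empty(n_reps)
    for b in range(n_reps):
        res = rng.choice(col, size=col.size, replace=True)
        c = GenotypeCounts(int((res == 0).sum()), int((res == 1).sum()), int((res == 2).sum()))
        if estimator == "tau":
            estimates[b] = estimate_tau(c)[0]
        elif estimator == "beta":
            assert tau is not None
            estimates[b] = estimate_dr(c, tau)[0]
        else:
            raise ModelError(f"unknown estimator {estimator!r}")
    return float(np.std(estimates, ddof=1))


def estimate_chromosome(
    g: GameteMatrix,
    chromosome: str,
    n_centromeric: int = 4,
    n_telomeric: int = 6,
) -> InheritanceEstimate:
    """Estimate PP, tau and beta for one chromosome.

    tau is the mean of per-marker closed-form estimates over up to
    ``n_centromeric`` markers with role "centromeric" (dispersion = their sd);
    PP = 1 - tau. beta is the mean over up to ``n_telomeric`` markers with
    role "telomeric", each estimated with the chromosome's fixed tau.
    """
    idx = g.markers_on(chromosome)
    cent = [j for j in idx if g.markers[j].role == "centromeric"][:n_centromeric]
    telo = [j for j in idx if g.markers[j].role == "telomeric"][:n_telomeric]
    if not cent:
        raise ModelError(f"no centromeric marker on chromosome {chromosome}")
    tau_by_marker = {
        g.markers[j].marker_id: estimate_tau(counts_at(g, j))[0] for j in cent
    }
    taus = np.array(list(tau_by_marker.values()))
    tau = float(taus.mean())
    tau_sd = float(taus.std(ddof=1)) if taus.size > 1 else 0.0
    beta_by_marker: dict[str, float] = {}
    if tau > 0.0:
        for j in telo:
            beta_by_marker[g.markers[j].marker_id] = estimate_dr(counts_at(g, j), tau)[0]
    betas = np.array(list(beta_by_marker.values()))
    beta = float(betas.mean()) if betas.size else float("nan")
    beta_sd = float(betas.std(ddof=1)) if betas.size > 1 else 0.0
    return InheritanceEstimate(
        chromosome=chromosome,
        PP=1.0 - tau,
        tau=tau,
        beta=beta,
        PP_sd=tau_sd,
        beta_sd=beta_sd,
        n_centromeric=len(cent),
        n_telomeric=len(beta_by_marker),
        tau_per_marker=tau_by_marker,
        beta_per_marker=beta_by_marker,
    )


def estimate_all(g: GameteMatrix, **kwargs) -> list[InheritanceEstimate]:
    return [estimate_chromosome(g, c, **kwargs) for c in g.chromosomes()]


def phr_summary(g: GameteMatrix) -> PhrSummary:
    """Heterozygosity-restitution fractions per marker, gamete and chromosome.

    Per-marker PHR is the fraction of observed gametes that are AM; the
    chromosome value is the unweighted mean over its markers. The percentage
    of gametes with full heterozygosity (resp. M or A homozygosity) on a
    chromosome requires every observed marker of that chromosome to be in the
    respective state (gametes with no observed marker are excluded).
    """
    geno = g.genotype
    obs = geno != MISSING
    het = geno == 1

    marker_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        marker_phr = np.where(marker_obs > 0, het.sum(axis=0) / np.maximum(marker_obs, 1), np.nan)
    per_marker = pd.DataFrame(
        {
            "marker_id": g.marker_ids,
            "chromosome": [m.chromosome for m in g.markers],
            "role": [m.role for m in g.markers],
            "n_obs": marker_obs,
            "phr": marker_phr,
        }
    )
    if (marker_obs == 0).any():
        bad = per_marker.loc[marker_obs == 0, "marker_id"].tolist()
        logger.warning("PHR undefined (no observed gametes) for markers: %s", bad)

    gamete_obs = obs.sum(axis=1)
    per_gamete = pd.DataFrame(
        {
            "gamete_id": g.gametes,
            "n_obs": gamete_obs,
            "phr": np.where(gamete_obs > 0, het.sum(axis=1) / np.maximum(gamete_obs, 1), np.nan),
        }
    )

    rows = []
    for chrom in g.chromosomes():
        idx = np.array(g.markers_on(chrom))
        phr_vals = marker_phr[idx]
        phr_vals = phr_vals[~np.isnan(phr_vals)]
        sub_obs = obs[:, idx]
        covered = sub_obs.any(axis=1)
        state_pct = {}
        for label, code in (("het", 1), ("M_hom", 2), ("A_hom", 0)):
            full = ((geno[:, idx] == code) | ~sub_obs).all(axis=1) & covered
            state_pct[f"pct_full_{label}"] = 100.0 * full.sum() / max(covered.sum(), 1)
        rows.append(
            {
                "chromosome": chrom,
                "n_markers": len(idx),
                "phr_mean": float(phr_vals.mean()) if phr_vals.size else float("nan"),
                "phr_sd": float(phr_vals.std(ddof=1)) if phr_vals.size > 1 else 0.0,
                **state_pct,
            }
        )
    per_chromosome = pd.DataFrame(rows)
    valid = per_marker["phr"].dropna()
    genome_mean = float(valid.mean()) if len(valid) else float("nan")
    return PhrSummary(
        per_marker=per_marker,
        per_gamete=per_gamete,
        per_chromosome=per_chromosome,
        genome_mean=genome_mean,
    )


def estimates_table(estimates: list[InheritanceEstimate]) -> pd.DataFrame:
    """Per-chromosome PP/tau/beta table (one row per chromosome)."""
    return pd.DataFrame(
        [
            {
                "chromosome": e.chromosome,
                "PP": e.PP,
                "PP_sd": e.PP_sd,
                "tau": e.tau,
                "tau_sd": e.PP_sd,
                "beta": e.beta,
                "beta_sd": e.beta_sd,
                "n_centromeric": e.n_centromeric,
                "n_telomeric": e.n_telomeric,
            }
            for e in estimates
        ]
    )
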