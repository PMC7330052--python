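"""Tetraploid meiosis simulator for a duplex (AAMM) x nulliplex (AA) cross.

Two generation modes:

* ``locus_wise`` draws every marker x gamete genotype independently from the
  single-locus model (`inheritance.genotype_probs`) with a per-marker double
  reduction that ramps linearly from 0 at the centromere to the chromosome's
  telomeric value at each end. This is the estimator-testing default: the
  requested (PP, beta) are exact marginals.
* ``chromosome_wise`` simulates whole meioses. With probability PP the
  meiosis pairs homologues exclusively and the gamete is AM everywhere; with
  probability tau one of the three bivalent configurations is drawn
  uniformly. Heterogenetic bivalents produce chromatids whose chromosome of
  origin starts at random and switches along the genetic map following a
  Poisson crossover process at 1 event/Morgan (Haldane, no interference);
  the process is realised through its exact marker-interval parities.
  Double reduction is approximated: within random-pairing meioses, with
  probability 6*beta a gamete is forced homozygous (shared chromatid origin)
  distal to an exponentially distributed first-crossover point on one arm
  and heterozygous proximal to it.

Gamete matrices convert to triploid dose matrices by adding the haploid A
contribution of the nulliplex parent (AA -> 0, AM -> 1, MM -> 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import ThetaAnchors
from .data import MISSING, DoseMatrix, GameteMatrix, MarkerDef
from .inheritance import BETA_MAX, genotype_probs


class SimError(ValueError):
    pass


@dataclass(frozen=True)
class SimMarker:
    marker_id: str
    position_bp: int
    position_cm: float
    role: str = "other"


@dataclass
class SimChromosome:
    chromosome: str
    length_cm: float
    markers: list[SimMarker]
    centromere_cm: float
    pp: float
    beta_telomeric: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pp <= 1.0:
            raise SimError(f"pp={self.pp} outside [0, 1]")
        # printed-table values round 1/6 to 0.167; snap within rounding slack
        if not 0.0 <= self.beta_telomeric <= BETA_MAX + 5e-4:
            raise SimError(f"beta_telomeric={self.beta_telomeric} outside [0, 1/6]")
        self.beta_telomeric = min(self.beta_telomeric, BETA_MAX)
        if not 0.0 <= self.centromere_cm <= self.length_cm:
            raise SimError("centromere outside chromosome")
        for m in self.markers:
            if not 0.0 <= m.position_cm <= self.length_cm:
                raise SimError(f"marker {m.marker_id} cM position outside chromosome")

    def beta_at(self, position_cm: float) -> float:
        """Linear double-reduction ramp: 0 at the centromere, telomeric at ends."""
        c, L = self.centromere_cm, self.length_cm
        if position_cm >= c:
            arm = L - c
            frac = (position_cm - c) / arm if arm > 0 else 0.0
        else:
            frac = (c - position_cm) / c if c > 0 else 0.0
        return self.beta_telomeric * frac

    def marker_defs(self) -> list[MarkerDef]:
        return [
            MarkerDef(m.marker_id, self.chromosome, m.position_bp, m.role)
            for m in self.markers
        ]


@dataclass
class SimConfig:
    chromosomes: list[SimChromosome]
    n_gametes: int
    seed: int
    mode: str = "locus_wise"  # locus_wise | chromosome_wise
    missing_rate: float = 0.0
    signal_noise_sd: float = 2.0
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_gametes < 1:
            raise SimError("n_gametes must be >= 1")
        if self.mode not in ("locus_wise", "chromosome_wise"):
            raise SimError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimError("missing_rate must be in [0, 1)")


def make_chromosome(
    chromosome: str,
    n_markers: int,
    length_cm: float,
    span_bp: int,
    pp: float,
    beta_telomeric: float = 0.0,
    centromere_frac: float = 0.5,
    n_centromeric: int = 4,
    n_telomeric_per_arm: int = 3,
) -> SimChromosome:
    """Evenly spaced marker panel with role assignment around the centromere."""
    if n_markers < 1:
        raise SimError("need at least one marker")
    cm = length_cm * (np.arange(n_markers) + 0.5) / n_markers
    bp = np.rint(span_bp * (np.arange(n_markers) + 0.5) / n_markers).astype(int)
    centromere_cm = centromere_frac * length_cm
    roles = ["other"] * n_markers
    order_by_cen = np.argsort(np.abs(cm - centromere_cm), kind="stable")
    for j in order_by_cen[:n_centromeric]:
        roles[j] = "centromeric"
    for j in range(min(n_telomeric_per_arm, n_markers)):
        if roles[j] == "other":
            roles[j] = "telomeric"
        if roles[n_markers - 1 - j] == "other":
            roles[n_markers - 1 - j] = "telomeric"
    markers = [
        SimMarker(f"S{chromosome}_{int(bp[j])}", int(bp[j]), float(cm[j]), roles[j])
        for j in range(n_markers)
    ]
    return SimChromosome(
        chromosome=chromosome,
        length_cm=length_cm,
        markers=markers,
        centromere_cm=centromere_cm,
        pp=pp,
        beta_telomeric=beta_telomeric,
    )


# Per-chromosome pairing/double-reduction parameters and panel sizes used for
# the default preset emulating a 158-marker, 269-gamete doubled-diploid lime
# study design (9 chromosomes, disomic-leaning mixed inheritance).
GIANT_KEY_PP = (0.751, 0.82, 0.749, 0.781, 0.633, 0.669, 0.733, 0.995, 0.945)
GIANT_KEY_BETA = (0.136, 0.118, 0.167, 0.084, 0.109, 0.007, 0.132, 0.167, 0.167)
GIANT_KEY_N_MARKERS = (19, 19, 25, 19, 14, 13, 14, 15, 20)
GIANT_KEY_SPAN_MB = (26.32, 33.11, 50.8, 25.35, 43.06, 24.97, 18.87, 23.79, 30.03)
GIANT_KEY_CM_PER_MB = 3.0  # diploid-like rate used to set simulated map lengths


def giant_key(
    n_gametes: int = 269,
    seed: int = 20200625,
    mode: str = "locus_wise",
    missing_rate: float = 0.02,
) -> SimConfig:
    """Default preset: 9 chromosomes, 158 markers, 269 gametes."""
    chromosomes = [
        make_chromosome(
            chromosome=str(c + 1),
            n_markers=GIANT_KEY_N_MARKERS[c],
            length_cm=GIANT_KEY_CM_PER_MB * GIANT_KEY_SPAN_MB[c],
            span_bp=int(GIANT_KEY_SPAN_MB[c] * 1e6),
            pp=GIANT_KEY_PP[c],
            beta_telomeric=GIANT_KEY_BETA[c],
        )
        for c in range(9)
    ]
    return SimConfig(
        chromosomes=chromosomes,
        n_gametes=n_gametes,
        seed=seed,
        mode=mode,
        missing_rate=missing_rate,
    )


def haldane_r(d_cm: float) -> float:
    """Haldane recombination fraction for a map distance in cM."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def _mask_missing(geno: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate > 0.0:
        geno = geno.copy()
        geno[rng.random(geno.shape) < rate] = MISSING
    return geno


def _gamete_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def simulate_locus_wise(cfg: SimConfig) -> GameteMatrix:
    """Independent draws per marker from the single-locus genotype model."""
    if cfg.mode != "locus_wise":
        raise SimError("config mode is not locus_wise")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_gametes
    cols, defs = [], []
    for chrom in cfg.chromosomes:
        for m in chrom.markers:
            p_aa, p_am, _ = genotype_probs(chrom.pp, chrom.beta_at(m.position_cm))
            u = rng.random(n)
            geno = ((u >= p_aa).astype(np.int8) + (u >= p_aa + p_am).astype(np.int8))
            cols.append(geno)
        defs.extend(chrom.marker_defs())
    geno = np.column_stack(cols)
    geno = _mask_missing(geno, cfg.missing_rate, rng)
    return GameteMatrix(gametes=_gamete_ids(n), markers=defs, genotype=geno)


def _heterogenetic_chromatids(
    n: int, cm: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Chromatid M-origin indicators at marker positions, plus flip counts.

    The Poisson crossover process is realised through its exact interval
    parities: the origin flips between adjacent markers with the Haldane
    probability of the interval.
    """
    k = cm.size
    origin = np.empty((n, k), dtype=np.int8)
    origin[:, 0] = rng.random(n) < 0.5
    flips = np.zeros(n, dtype=np.int64)
    for j in range(1, k):
        r = haldane_r(cm[j] - cm[j - 1])
        flip = rng.random(n) < r
        origin[:, j] = origin[:, j - 1] ^ flip
        flips += flip
    return origin, flips


def simulate_chromosome_wise(cfg: SimConfig) -> tuple[GameteMatrix, pd.DataFrame]:
    """Whole-meiosis simulation; returns gametes plus true crossover counts.

    The second return value has one row per gamete x chromosome with the
    number of chromatid origin switches (marker-interval parity events).
    """
    if cfg.mode != "chromosome_wise":
        raise SimError("config mode is not chromosome_wise")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_gametes
    blocks, defs, truth_rows = [], [], []
    for chrom in cfg.chromosomes:
        cm = np.array([m.position_cm for m in chrom.markers])
        order = np.argsort(cm, kind="stable")
        cm_sorted = cm[order]
        k = cm.size
        geno = np.ones((n, k), dtype=np.int8)  # PP meioses: AM everywhere
        xo = np.zeros(n, dtype=np.int64)
        random_pairing = rng.random(n) >= chrom.pp
        idx = np.flatnonzero(random_pairing)
        if idx.size:
            config = rng.integers(0, 3, size=idx.size)
            het = idx[config > 0]  # heterogenetic configurations pair M with A
            if het.size:
                o1, f1 = _heterogenetic_chromatids(het.size, cm_sorted, rng)
                o2, f2 = _heterogenetic_chromatids(het.size, cm_sorted, rng)
                sub = np.empty((het.size, k), dtype=np.int8)
                sub[:, order] = o1 + o2
                geno[het] = sub
                xo[het] = f1 + f2
            # approximate double reduction: forced shared origin distal to an
            # exponential first-crossover point on one arm
            if chrom.beta_telomeric > 0.0:
                p_dr = min(6.0 * chrom.beta_telomeric, 1.0)
                dr = idx[rng.random(idx.size) < p_dr]
                if dr.size:
                    shared = rng.integers(0, 2, size=dr.size).astype(np.int8)
                    arm_right = rng.random(dr.size) < 0.5
                    x_cm = rng.exponential(scale=100.0, size=dr.size)
                    marker_right = cm > chrom.centromere_cm
                    dist = np.abs(cm - chrom.centromere_cm)
                    on_arm = arm_right[:, None] == marker_right[None, :]
                    distal = on_arm & (dist[None, :] > x_cm[:, None])
                    proximal = on_arm & ~distal
                    sub = geno[dr]
                    sub = np.where(distal, (2 * shared)[:, None], sub)
                    sub = np.where(proximal, np.int8(1), sub)
                    geno[dr] = sub
        blocks.append(geno)
        defs.extend(chrom.marker_defs())
        truth_rows.extend(
            {"gamete_id": gid, "chromosome": chrom.chromosome, "n_crossovers": int(c)}
            for gid, c in zip(_gamete_ids(n), xo)
        )
    geno = np.column_stack(blocks)
    geno = _mask_missing(geno, cfg.missing_rate, rng)
    gm = GameteMatrix(gametes=_gamete_ids(n), markers=defs, genotype=geno)
    return gm, pd.DataFrame(truth_rows)


def simulate(cfg: SimConfig) -> GameteMatrix:
    """Dispatch on ``cfg.mode``; chromosome-wise truth counts are discarded."""
    if cfg.mode == "locus_wise":
        return simulate_locus_wise(cfg)
    gm, _ = simulate_chromosome_wise(cfg)
    return gm


def make_triploid_doses(g: GameteMatrix) -> DoseMatrix:
    """Triploid M doses after fertilisation by a haploid A gamete."""
    dose = g.genotype.astype(float)
    dose[g.genotype == MISSING] = np.nan
    return DoseMatrix(samples=list(g.gametes), markers=list(g.markers), dose=dose)


def simulate_signals(
    d: DoseMatrix,
    anchors: ThetaAnchors,
    noise_sd: float,
    seed: int,
    n_controls_per_class: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy two-channel signals for a dose matrix, plus control records.

    Each dose maps to its expected theta (piecewise-linear at f = d/3),
    Gaussian angular noise of ``noise_sd`` degrees is added, and the radial
    norm is 1 +/- 10% (uniform). Control records (diploid AA, MM and 1:1
    heterozygous references) are emitted per marker with the same noise.
    """
    rng = np.random.default_rng(seed)

    def point(theta_deg: float) -> tuple[float, float]:
        t = min(max(theta_deg + rng.normal(0.0, noise_sd), 0.0), 90.0)
        radius = 1.0 + rng.uniform(-0.1, 0.1)
        rad = math.radians(t)
        return radius * math.cos(rad), radius * math.sin(rad)

    sig_rows, ctl_rows = [], []
    for j, mid in enumerate(d.marker_ids):
        for i, sid in enumerate(d.samples):
            dose = d.dose[i, j]
            if np.isnan(dose):
                continue
            x, y = point(anchors.expected_theta(dose / 3.0))
            sig_rows.append(
                {"sample_id": sid, "marker_id": mid, "x_signal": x, "y_signal": y}
            )
        for cls, f in (("AA", 0.0), ("AM", 0.5), ("MM", 1.0)):
            for c in range(n_controls_per_class):
                x, y = point(anchors.expected_theta(f))
                ctl_rows.append(
                    {
                        "sample_id": f"ctl_{cls}_{c + 1}",
                        "marker_id": mid,
                        "genotype": cls,
                        "x_signal": x,
                        "y_signal": y,
                    }
                )
    return pd.DataFrame(sig_rows), pd.DataFrame(ctl_rows)


def config_from_dict(payload: dict) -> SimConfig:
    """Build a SimConfig from a JSON-style dict (or the named preset)."""
    if "preset" in payload:
        if payload["preset"] != "giant_key":
            raise SimError(f"unknown preset {payload['preset']!r}")
        kwargs = {
            k: payload[k]
            for k in ("n_gametes", "seed", "mode", "missing_rate")
            if k in payload
        }
        return giant_key(**kwargs)
    chromosomes = []
    for ch in payload["chromosomes"]:
        if "markers" in ch:
            markers = [
                SimMarker(
                    m["marker_id"], int(m["position_bp"]), float(m["position_cm"]),
                    m.get("role", "other"),
                )
                for m in ch["markers"]
            ]
            chromosomes.append(
                SimChromosome(
                    chromosome=str(ch["chromosome"]),
                    length_cm=float(ch["length_cm"]),
                    markers=markers,
                    centromere_cm=float(ch["centromere_cm"]),
                    pp=float(ch["pp"]),
                    beta_telomeric=float(ch.get("beta_telomeric", 0.0)),
                )
            )
        else:
            chromosomes.append(
                make_chromosome(
                    chromosome=str(ch["chromosome"]),
                    n_markers=int(ch["n_markers"]),
                    length_cm=float(ch["length_cm"]),
                    span_bp=int(ch.get("span_bp", 1_000_000 * ch["length_cm"])),
                    pp=float(ch["pp"]),
                    beta_telomeric=float(ch.get("beta_telomeric", 0.0)),
                    centromere_frac=float(ch.get("centromere_frac", 0.5)),
                )
            )
    return SimConfig(
        chromosomes=chromosomes,
        n_gametes=int(payload["n_gametes"]),
        seed=int(payload["seed"]),
        mode=payload.get("mode", "locus_wise"),
        missing_rate=float(payload.get("missing_rate", 0.0)),
        signal_noise_sd=float(payload.get("signal_noise_sd", 2.0)),
    )
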