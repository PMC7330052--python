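"""Graphical genotypes, crossover counting and genome-composition summaries.

Crossovers are counted with a minimal-switch convention along markers
ordered by physical position: with genotype codes AA=0, AM=1, MM=2 the cost
of an adjacent transition is ``|a - b|`` (AM<->hom = 1 switch, AA<->MM = 2,
both chromatid origins change). Missing markers are bridged: the transition
is computed between the nearest observed flanking markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, GameteMatrix

STATE_LABELS = {0: "AA", 1: "AM", 2: "MM"}


@dataclass
class GraphicalGenotype:
    """Run-length encoding of one gamete along one chromosome."""

    gamete_id: str
    chromosome: str
    marker_ids: list[str]
    positions_bp: list[int]
    states: list[int]  # observed states only, in bp order
    runs: list[tuple[str, int, int]] = field(default_factory=list)  # (state, start_bp, end_bp)
    all_missing: bool = False


@dataclass
class RecombSummary:
    per_gamete: pd.DataFrame  # gamete_id, chromosome, n_crossovers, n_obs
    genome_per_gamete: pd.DataFrame  # gamete_id, n_crossovers, frac_het/M_hom/A_hom
    crossover_distribution: pd.DataFrame  # n_crossovers, n_gametes, pct, cum_pct
    mean_crossovers: float
    mean_frac_het: float
    mean_frac_M_hom: float
    mean_frac_A_hom: float


def count_crossovers(states: np.ndarray | list[int]) -> int:
    """Minimal chromosome-origin switches along an ordered genotype sequence.

    ``states`` uses codes AA=0, AM=1, MM=2, missing=-1; missing entries are
    skipped (bridged between observed flanks). Fewer than two observed
    markers yield 0.
    """
    arr = np.asarray(states)
    obs = arr[arr != MISSING]
    if obs.size < 2:
        return 0
    return int(np.abs(np.diff(obs.astype(int))).sum())


def graphical_genotypes(g: GameteMatrix) -> list[GraphicalGenotype]:
    """Run-length encode every gamete x chromosome track."""
    out: list[GraphicalGenotype] = []
    for chrom in g.chromosomes():
        idx = g.markers_on(chrom)
        mids = [g.markers[j].marker_id for j in idx]
        pos = [g.markers[j].position_bp for j in idx]
        for i, gid in enumerate(g.gametes):
            track = g.genotype[i, idx]
            keep = track != MISSING
            states = track[keep].astype(int).tolist()
            opos = [p for p, k in zip(pos, keep) if k]
            omids = [m for m, k in zip(mids, keep) if k]
            gg = GraphicalGenotype(
                gamete_id=gid,
                chromosome=chrom,
                marker_ids=omids,
                positions_bp=opos,
                states=states,
                all_missing=not states,
            )
            run_start = 0
            for k in range(1, len(states) + 1):
                if k == len(states) or states[k] != states[run_start]:
                    gg.runs.append(
                        (STATE_LABELS[states[run_start]], opos[run_start], opos[k - 1])
                    )
                    run_start = k
            out.append(gg)
    return out


def runs_table(ggs: list[GraphicalGenotype]) -> pd.DataFrame:
    rows = [
        {
            "gamete_id": gg.gamete_id,
            "chromosome": gg.chromosome,
            "state": state,
            "start_bp": start,
            "end_bp": end,
        }
        for gg in ggs
        for state, start, end in gg.runs
    ]
    return pd.DataFrame(rows, columns=["gamete_id", "chromosome", "state", "start_bp", "end_bp"])


def genome_composition(g: GameteMatrix) -> RecombSummary:
    """Crossover counts and het/hom genome fractions per gamete and cohort."""
    per_gamete_rows = []
    genome_counts = np.zeros(g.n_gametes, dtype=int)
    for chrom in g.chromosomes():
        idx = g.markers_on(chrom)
        for i, gid in enumerate(g.gametes):
            track = g.genotype[i, idx]
            n_obs = int((track != MISSING).sum())
            nco = count_crossovers(track)
            genome_counts[i] += nco
            per_gamete_rows.append(
                {"gamete_id": gid, "chromosome": chrom, "n_crossovers": nco, "n_obs": n_obs}
            )
    per_gamete = pd.DataFrame(per_gamete_rows)

    obs = g.genotype != MISSING
    n_obs_genome = obs.sum(axis=1)
    safe = np.maximum(n_obs_genome, 1)
    frac = {
        label: np.where(n_obs_genome > 0, (g.genotype == code).sum(axis=1) / safe, np.nan)
        for label, code in (("het", 1), ("M_hom", 2), ("A_hom", 0))
    }
    genome_per_gamete = pd.DataFrame(
        {
            "gamete_id": g.gametes,
            "n_crossovers": genome_counts,
            "frac_het": frac["het"],
            "frac_M_hom": frac["M_hom"],
            "frac_A_hom": frac["A_hom"],
        }
    )

    values, counts = np.unique(genome_counts, return_counts=True)
    pct = 100.0 * counts / g.n_gametes
    crossover_distribution = pd.DataFrame(
        {
            "n_crossovers": values,
            "n_gametes": counts,
            "pct": pct,
            "cum_pct": np.cumsum(pct),
        }
    )
    return RecombSummary(
        per_gamete=per_gamete,
        genome_per_gamete=genome_per_gamete,
        crossover_distribution=crossover_distribution,
        mean_crossovers=float(genome_counts.mean()),
        mean_frac_het=float(np.nanmean(frac["het"])),
        mean_frac_M_hom=float(np.nanmean(frac["M_hom"])),
        mean_frac_A_hom=float(np.nanmean(frac["A_hom"])),
    )


def plot_graphical_genotypes(ggs: list[GraphicalGenotype], path: str) -> None:
    """Simple horizontal-bar rendering of runs, one row per gamete track."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"AA": "#1f77b4", "AM": "#bbbbbb", "MM": "#d62728"}
    tracks = [gg for gg in ggs if gg.runs]
    fig, ax = plt.subplots(figsize=(10, max(2, 0.06 * len(tracks))))
    for row, gg in enumerate(tracks):
        for state, start, end in gg.runs:
            ax.barh(row, max(end - start, 1), left=start, color=colors[state], height=0.9)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("gamete x chromosome track")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
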