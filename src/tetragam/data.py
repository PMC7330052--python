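"""Core data model and I/O.

Dose matrices hold the number of M-allele copies (0/1/2) observed in each
triploid hybrid at each diagnostic SNP; because the second parent is a
nulliplex (AA) contributing a single A allele, the triploid dose maps
one-to-one onto the genotype of the diploid gamete produced by the
tetraploid parent (0 -> AA, 1 -> AM, 2 -> MM).

Genotypes are stored as small integer codes (AA=0, AM=1, MM=2, missing=-1)
so that the dose of the M allele and the genotype code coincide.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1
GENOTYPE_STATES = ("AA", "AM", "MM")
MISSING_TOKENS = {"", "NA", "NaN", "nan", "-1", "."}

ROLES = ("centromeric", "telomeric", "other")


class DataError(ValueError):
    """Raised on malformed or inconsistent input data."""


@dataclass(frozen=True)
class MarkerDef:
    """One SNP locus with genome coordinates and a pairing-analysis role.

    ``position_bp`` is 1-based, matching marker names of the form
    ``S<chrom>_<pos>``. ``role`` designates whether the marker is used for
    tetrasomic-rate estimation (centromeric), double-reduction estimation
    (telomeric) or neither (other); roles are assigned by the user since
    centromere coordinates are configuration, not data.
    """

    marker_id: str
    chromosome: str
    position_bp: int
    role: str = "other"

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise DataError(f"negative position_bp for {self.marker_id}")
        if self.role not in ROLES:
            raise DataError(
                f"unknown role {self.role!r} for {self.marker_id}; "
                f"expected one of {ROLES}"
            )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what} id: {i}")
        seen.add(i)


@dataclass
class DoseMatrix:
    """M-allele doses (0/1/2, NaN = missing) per sample x marker."""

    samples: list[str]
    markers: list[MarkerDef]
    dose: np.ndarray  # float array (n_samples, n_markers), NaN = missing

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != (len(self.samples), len(self.markers)):
            raise DataError(
                f"dose shape {self.dose.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        _check_unique(self.samples, "sample")
        _check_unique([m.marker_id for m in self.markers], "marker")
        observed = self.dose[~np.isnan(self.dose)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(observed) - {0.0, 1.0, 2.0})
            raise DataError(f"dose out of range: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dose, index=self.samples, columns=self.marker_ids)

    def subset(
        self, sample_idx: np.ndarray | None = None, marker_idx: np.ndarray | None = None
    ) -> "DoseMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return DoseMatrix(
            samples=[self.samples[i] for i in si],
            markers=[self.markers[j] for j in mi],
            dose=self.dose[np.ix_(si, mi)].copy(),
        )


@dataclass
class GameteMatrix:
    """Inferred diploid-gamete genotypes per gamete x marker.

    ``genotype`` is int8 with codes AA=0, AM=1, MM=2, missing=-1. One gamete
    per triploid hybrid (the tetraploid parent's contribution).
    """

    gametes: list[str]
    markers: list[MarkerDef]
    genotype: np.ndarray

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=np.int8)
        if self.genotype.shape != (len(self.gametes), len(self.markers)):
            raise DataError("genotype shape inconsistent with gametes x markers")
        _check_unique(self.gametes, "gamete")
        _check_unique([m.marker_id for m in self.markers], "marker")
        if not np.isin(self.genotype, (-1, 0, 1, 2)).all():
            raise DataError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_gametes(self) -> int:
        return len(self.gametes)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def to_frame(self) -> pd.DataFrame:
        """Genotypes as strings (AA/AM/MM) with NA for missing."""
        labels = np.array(["NA", "AA", "AM", "MM"], dtype=object)
        return pd.DataFrame(
            labels[self.genotype + 1], index=self.gametes, columns=self.marker_ids
        )

    def markers_on(self, chromosome: str) -> list[int]:
        """Column indices of markers on a chromosome, ordered by bp."""
        idx = [j for j, m in enumerate(self.markers) if m.chromosome == chromosome]
        return sorted(idx, key=lambda j: self.markers[j].position_bp)

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for m in self.markers:
            if m.chromosome not in out:
                out.append(m.chromosome)
        return out


@dataclass
class QcReport:
    """Record of markers/samples removed by QC, with reasons."""

    removed_markers: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def merged(self, other: "QcReport") -> "QcReport":
        return QcReport(
            removed_markers=self.removed_markers + other.removed_markers,
            removed_samples=self.removed_samples + other.removed_samples,
            thresholds={**self.thresholds, **other.thresholds},
        )

    def to_dict(self) -> dict:
        return {
            "removed_markers": [
                {"marker_id": m, "reason": r} for m, r in self.removed_markers
            ],
            "removed_samples": [
                {"sample_id": s, "reason": r} for s, r in self.removed_samples
            ],
            "thresholds": dict(self.thresholds),
        }


# ---------------------------------------------------------------------------
# I/O

def read_marker_metadata(path: str | Path) -> dict[str, MarkerDef]:
    """Read marker metadata TSV (marker_id, chromosome, position_bp, role)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker_id", "chromosome", "position_bp"}
    if not required.issubset(df.columns):
        raise DataError(
            f"marker metadata must have columns {sorted(required)}; got {list(df.columns)}"
        )
    if "role" not in df.columns:
        df["role"] = "other"
    defs: dict[str, MarkerDef] = {}
    for row in df.itertuples(index=False):
        if row.marker_id in defs:
            raise DataError(f"duplicate marker id in metadata: {row.marker_id}")
        defs[row.marker_id] = MarkerDef(
            marker_id=row.marker_id,
            chromosome=str(row.chromosome),
            position_bp=int(row.position_bp),
            role=str(row.role),
        )
    return defs


def _parse_dose_token(token: str, marker_id: str) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return np.nan
    try:
        value = float(token)
    except ValueError:
        raise DataError(f"unparseable dose {token!r} at marker {marker_id}") from None
    if value not in (0.0, 1.0, 2.0):
        raise DataError(f"dose out of range: {token!r} at marker {marker_id}")
    return value


def read_dose_matrix(path: str | Path, markers_path: str | Path) -> DoseMatrix:
    """Read a dose matrix (samples in rows, markers in columns) plus metadata.

    The table is TSV or CSV (sniffed from the header line); the first column
    holds sample ids and the header row the marker ids. Accepted missing
    tokens: "", "NA", "NaN", "-1", ".".
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    # pandas mangles duplicated header names, so check the raw header first
    raw_ids = [tok.strip() for tok in header.rstrip("\n").split(sep)][1:]
    _check_unique(raw_ids, "marker")
    df = pd.read_csv(path, sep=sep, dtype=str, index_col=0, keep_default_na=False)
    marker_ids = [str(c) for c in df.columns]
    _check_unique([str(s) for s in df.index], "sample")
    meta = read_marker_metadata(markers_path)
    missing_meta = [m for m in marker_ids if m not in meta]
    if missing_meta:
        raise DataError(f"markers absent from metadata: {missing_meta[:5]}")
    dose = np.empty(df.shape, dtype=float)
    for j, mid in enumerate(marker_ids):
        col = df.iloc[:, j]
        dose[:, j] = [_parse_dose_token(str(v), mid) for v in col]
    return DoseMatrix(
        samples=[str(s) for s in df.index],
        markers=[meta[m] for m in marker_ids],
        dose=dose,
    )


def write_dose_matrix(m: DoseMatrix, path: str | Path) -> None:
    df = m.to_frame()
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_marker_metadata(markers: Iterable[MarkerDef], path: str | Path) -> None:
    rows = [dataclasses.asdict(m) for m in markers]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gamete_matrix(g: GameteMatrix, path: str | Path) -> None:
    df = g.to_frame()
    df.index.name = "gamete_id"
    df.to_csv(path, sep="\t")


def read_gamete_matrix(path: str | Path, markers_path: str | Path) -> GameteMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    meta = read_marker_metadata(markers_path)
    marker_ids = [str(c) for c in df.columns]
    missing_meta = [m for m in marker_ids if m not in meta]
    if missing_meta:
        raise DataError(f"markers absent from metadata: {missing_meta[:5]}")
    codes = {"AA": 0, "AM": 1, "MM": 2}
    geno = np.empty(df.shape, dtype=np.int8)
    for j in range(df.shape[1]):
        for i, tok in enumerate(df.iloc[:, j]):
            tok = str(tok).strip()
            if tok in MISSING_TOKENS:
                geno[i, j] = MISSING
            elif tok in codes:
                geno[i, j] = codes[tok]
            else:
                raise DataError(f"unknown genotype token {tok!r}")
    return GameteMatrix(
        gametes=[str(s) for s in df.index],
        markers=[meta[m] for m in marker_ids],
        genotype=geno,
    )


# ---------------------------------------------------------------------------
# QC

def filter_matrix(
    m: DoseMatrix,
    max_marker_missing: float = 0.10,
    max_sample_missing: float = 0.10,
) -> tuple[DoseMatrix, QcReport]:
    """Drop markers, then samples, whose missing fraction is >= threshold.

    Markers are filtered first on all samples; sample missingness is then
    recomputed on the retained markers only. "Less than 10% missing" is the
    retention rule, so a fraction exactly equal to the threshold is removed.
    """
    for t in (max_marker_missing, max_sample_missing):
        if not 0.0 <= t <= 1.0:
            raise DataError(f"threshold {t} outside [0, 1]")
    report = QcReport(
        thresholds={
            "max_marker_missing": max_marker_missing,
            "max_sample_missing": max_sample_missing,
        }
    )
    isna = np.isnan(m.dose)
    marker_missing = isna.mean(axis=0)
    keep_m = marker_missing < max_marker_missing
    for j in np.flatnonzero(~keep_m):
        report.removed_markers.append(
            (m.markers[j].marker_id, f"missing>threshold ({marker_missing[j]:.3f})")
        )
    if not keep_m.any():
        raise DataError("all markers removed by missingness filter")
    sample_missing = isna[:, keep_m].mean(axis=1)
    keep_s = sample_missing < max_sample_missing
    for i in np.flatnonzero(~keep_s):
        report.removed_samples.append(
            (m.samples[i], f"missing>threshold ({sample_missing[i]:.3f})")
        )
    if not keep_s.any():
        raise DataError("all samples removed by missingness filter")
    out = m.subset(np.flatnonzero(keep_s), np.flatnonzero(keep_m))
    return out, report


def _duplicate_mask(vectors: np.ndarray) -> np.ndarray:
    """True for rows identical (NaN-equal) to an earlier row."""
    n = vectors.shape[0]
    dup = np.zeros(n, dtype=bool)
    seen: dict[bytes, int] = {}
    filled = np.where(np.isnan(vectors), -9.0, vectors)
    for i in range(n):
        key = filled[i].tobytes()
        if key in seen:
            dup[i] = True
        else:
            seen[key] = i
    return dup


def dedupe(m: DoseMatrix) -> tuple[DoseMatrix, QcReport]:
    """Remove markers and samples carrying exactly duplicated vectors.

    Equality is exact on the full vector including the missingness pattern
    (missing is not a wildcard); the first occurrence in input order is kept.
    """
    report = QcReport()
    dup_m = _duplicate_mask(m.dose.T)
    for j in np.flatnonzero(dup_m):
        report.removed_markers.append((m.markers[j].marker_id, "duplicate"))
    m2 = m.subset(marker_idx=np.flatnonzero(~dup_m))
    dup_s = _duplicate_mask(m2.dose)
    for i in np.flatnonzero(dup_s):
        report.removed_samples.append((m2.samples[i], "duplicate"))
    out = m2.subset(sample_idx=np.flatnonzero(~dup_s))
    return out, report


# ---------------------------------------------------------------------------
# Gamete inference

def doses_to_gametes(m: DoseMatrix) -> GameteMatrix:
    """Infer diploid-gamete genotypes from triploid M doses (0/1/2 -> AA/AM/MM).

    Valid because the seed parent is nulliplex and contributes exactly one A
    allele: the M dose of the triploid is the M dose of the diploid gamete.
    """
    geno = np.where(np.isnan(m.dose), MISSING, m.dose).astype(np.int8)
    return GameteMatrix(gametes=list(m.samples), markers=list(m.markers), genotype=geno)


def gametes_to_doses(g: GameteMatrix) -> DoseMatrix:
    """Inverse of :func:`doses_to_gametes` (adds the haploid A gamete back)."""
    dose = g.genotype.astype(float)
    dose[g.genotype == MISSING] = np.nan
    return DoseMatrix(samples=list(g.gametes), markers=list(g.markers), dose=dose)
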