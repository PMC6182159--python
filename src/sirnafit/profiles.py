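"""Positional phenotype profiles, single-nucleotide distribution shifts,
seed-group summaries, library composition profiles, and profile comparison
(distances + principal coordinates).

A *positional profile* answers: over all oligos in a screen that happen to
carry nucleotide ``nt`` at guide position ``p``, what is the mean cell-count
z-score? Aggregated over all four nucleotides and all positions this yields
a 4 x L table whose structure is remarkably reproducible across screens,
cell lines and vendors for the cell-number phenotype.

Position 1 is excluded by default: commercial libraries have a strong
technical design bias there, so not all nucleotides are adequately covered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io import ScreenDataset, ValidationError, seed_of

ALPHABET = ("A", "C", "G", "T")


def _sequence_matrix(sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences as an integer matrix (n x Lmax), -1 past each oligo's end.

    Returns (codes, lengths). Handles mixed 19-21mer libraries: per-position
    statistics later use only the oligos long enough to cover that position.
    """
    lengths = np.array([len(s) for s in sequences])
    lmax = int(lengths.max())
    lut = np.full(128, -1, dtype=np.int8)
    for k, nt in enumerate(ALPHABET):
        lut[ord(nt)] = k
    codes = np.full((len(sequences), lmax), -1, dtype=np.int8)
    for i, s in enumerate(sequences):
        codes[i, : len(s)] = lut[np.frombuffer(s.encode(), dtype=np.uint8)]
    return codes, lengths


@dataclass
class PositionalProfile:
    """Mean phenotype (plus support count and CI half-width) per (nucleotide, position).

    ``values``/``counts``/``ci_halfwidth`` are 4 x L DataFrames indexed by
    A/C/G/T with 1-based position columns. Cells with fewer supporting oligos
    than ``min_count`` are undefined (NaN), never zero.
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    ci_halfwidth: pd.DataFrame
    positions: list[int]
    min_count: int = 1

    def flattened(self, center: bool = True) -> np.ndarray:
        """Profile as a flat vector (A/C/G/T x positions), optionally mean-centered."""
        v = self.values.loc[list(ALPHABET), self.positions].to_numpy().ravel()
        if center:
            v = v - np.nanmean(v)
        return v


@dataclass
class FrequencyProfile:
    """Relative nucleotide frequencies per position (each column sums to 1)."""

    freqs: pd.DataFrame  # 4 x L, index A/C/G/T

    def __post_init__(self):
        colsums = self.freqs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValidationError("frequency profile columns must each sum to 1")

    @property
    def positions(self) -> list[int]:
        return list(self.freqs.columns)

    def flattened(self, center: bool = True) -> np.ndarray:
        v = self.freqs.loc[list(ALPHABET)].to_numpy().ravel()
        if center:
            v = v - np.nanmean(v)
        return v

    @classmethod
    def uniform(cls, length: int) -> "FrequencyProfile":
        df = pd.DataFrame(
            0.25, index=list(ALPHABET), columns=range(1, length + 1)
        )
        return cls(df)


@dataclass
class ShiftSummary:
    """Phenotype shift caused by one nucleotide at one position (subset vs rest)."""

    position: int
    nucleotide: str
    mean_shift: float
    n_subset: int
    n_complement: int
    p_value: float


@dataclass
class SeedGroupSummary:
    """Oligos sharing one 7-mer seed (guide positions 2-8): per-screen mean phenotype."""

    seed: str
    n: int
    mean_phenotype: dict  # screen label -> mean z
    cross_screen_correlation_contribution: float = float("nan")


def build_positional_profile(
    dataset: ScreenDataset,
    min_count: int = 1,
    include_position_1: bool = False,
    ci: str = "bootstrap",
    n_boot: int = 1000,
    rng_seed: int = 0,
) -> PositionalProfile:
    """Aggregate mean phenotype per (nucleotide, position) over a screen.

    ``ci`` is ``"bootstrap"`` (nonparametric, ``n_boot`` resamples, seeded),
    ``"normal"`` (1.96 x standard error), or ``"none"``.
    """
    if len(dataset) == 0:
        raise ValidationError("cannot profile an empty dataset")
    codes, lengths = _sequence_matrix(dataset.sequences())
    z = dataset.phenotypes().to_numpy(dtype=float)
    lmax = codes.shape[1]
    first = 1 if include_position_1 else 2
    positions = [p for p in range(first, lmax + 1)]

    values = pd.DataFrame(np.nan, index=list(ALPHABET), columns=positions)
    counts = pd.DataFrame(0, index=list(ALPHABET), columns=positions)
    cihw = pd.DataFrame(np.nan, index=list(ALPHABET), columns=positions)
    rng = np.random.default_rng(rng_seed)

    any_defined = False
    for p in positions:
        col = codes[:, p - 1]
        for k, nt in enumerate(ALPHABET):
            mask = col == k
            n = int(mask.sum())
            counts.loc[nt, p] = n
            if n < max(min_count, 1):
                continue
            vals = z[mask]
            values.loc[nt, p] = vals.mean()
            any_defined = True
            if ci == "bootstrap" and n > 1:
                idx = rng.integers(0, n, size=(n_boot, n))
                bmeans = vals[idx].mean(axis=1)
                lo, hi = np.percentile(bmeans, [2.5, 97.5])
                cihw.loc[nt, p] = (hi - lo) / 2.0
            elif ci == "normal" and n > 1:
                cihw.loc[nt, p] = 1.96 * vals.std(ddof=1) / np.sqrt(n)
    if not any_defined:
        raise ValidationError(
            f"all profile cells undefined at min_count={min_count}: dataset too small"
        )
    return PositionalProfile(values, counts, cihw, positions, min_count)


def build_frequency_profile(dataset: ScreenDataset | list[str]) -> FrequencyProfile:
    """Per-position nucleotide composition of a library (all positions, incl. 1)."""
    sequences = dataset.sequences() if isinstance(dataset, ScreenDataset) else list(dataset)
    if not sequences:
        raise ValidationError("cannot profile an empty library")
    codes, _ = _sequence_matrix(sequences)
    lmax = codes.shape[1]
    freqs = pd.DataFrame(0.0, index=list(ALPHABET), columns=range(1, lmax + 1))
    for p in range(1, lmax + 1):
        col = codes[:, p - 1]
        covered = col >= 0
        n = covered.sum()
        if n == 0:
            raise ValidationError(f"no oligo covers position {p}")
        for k, nt in enumerate(ALPHABET):
            freqs.loc[nt, p] = (col == k).sum() / n
    return FrequencyProfile(freqs)


def conditional_shift(dataset: ScreenDataset, position: int, nucleotide: str) -> ShiftSummary:
    """Mean phenotype shift of oligos with ``nucleotide`` at ``position`` vs all others.

    Uses a two-sided Welch two-sample t-test for the p-value.
    """
    nucleotide = nucleotide.upper()
    if nucleotide not in ALPHABET:
        raise ValidationError(f"unknown nucleotide {nucleotide!r}")
    codes, _ = _sequence_matrix(dataset.sequences())
    if position < 1 or position > codes.shape[1]:
        raise ValidationError(f"position {position} outside the library's length range")
    z = dataset.phenotypes().to_numpy(dtype=float)
    col = codes[:, position - 1]
    covered = col >= 0
    subset = covered & (col == ALPHABET.index(nucleotide))
    complement = covered & ~subset
    if subset.sum() == 0:
        raise ValidationError(f"no oligo has {nucleotide} at position {position}")
    if subset.sum() < 2 or complement.sum() < 2:
        raise ValidationError(
            f"need >= 2 oligos in subset and complement at ({position}, {nucleotide})"
        )
    a, b = z[subset], z[complement]
    _, p = stats.ttest_ind(a, b, equal_var=False)
    return ShiftSummary(
        position=position,
        nucleotide=nucleotide,
        mean_shift=float(a.mean() - b.mean()),
        n_subset=int(subset.sum()),
        n_complement=int(complement.sum()),
        p_value=float(p),
    )


def seed_group_summary(
    datasets: ScreenDataset | list[ScreenDataset],
    min_count: int = 2,
) -> list[SeedGroupSummary]:
    """Group oligos by their 7-mer seed and summarize per-screen mean phenotypes.

    With two screens, each group also carries its contribution to the Pearson
    correlation of per-seed means across the screens (contributions sum to r).
    Groups smaller than ``min_count`` in any screen are omitted.
    """
    if isinstance(datasets, ScreenDataset):
        datasets = [datasets]
    if not 1 <= len(datasets) <= 2:
        raise ValidationError("seed_group_summary takes one or two datasets")

    frames = []
    for i, ds in enumerate(datasets):
        df = ds.to_frame()
        label = df["screen"].iloc[0] if len(df) and df["screen"].iloc[0] else f"screen{i + 1}"
        df["_seed"] = [seed_of(s) for s in df["guide_seq"]]
        g = df.groupby("_seed")["phenotype"].agg(["mean", "size"])
        g.columns = [f"mean_{label}", f"n_{label}"]
        frames.append((label, g))

    merged = frames[0][1]
    labels = [frames[0][0]]
    for label, g in frames[1:]:
        merged = merged.join(g, how="inner")
        labels.append(label)
    for label in labels:
        merged = merged[merged[f"n_{label}"] >= min_count]

    contrib = pd.Series(np.nan, index=merged.index)
    if len(labels) == 2 and len(merged) >= 3:
        m1 = merged[f"mean_{labels[0]}"]
        m2 = merged[f"mean_{labels[1]}"]
        z1 = (m1 - m1.mean()) / m1.std(ddof=1)
        z2 = (m2 - m2.mean()) / m2.std(ddof=1)
        contrib = z1 * z2 / (len(merged) - 1)

    out = []
    for seed, row in merged.iterrows():
        out.append(
            SeedGroupSummary(
                seed=str(seed),
                n=int(min(row[f"n_{lb}"] for lb in labels)),
                mean_phenotype={lb: float(row[f"mean_{lb}"]) for lb in labels},
                cross_screen_correlation_contribution=float(contrib.loc[seed]),
            )
        )
    out.sort(key=lambda s: s.mean_phenotype[labels[0]])
    return out


def profile_distance_matrix(
    profiles: list[PositionalProfile | FrequencyProfile],
    center: bool = True,
) -> np.ndarray:
    """Euclidean distances between flattened (and, by default, mean-centered) profiles.

    Centering removes per-screen offsets so that phenotype profiles (z units)
    and library composition profiles (frequency units) compare by shape.
    Cells undefined in any profile are dropped from all of them.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles")
    vecs = [p.flattened(center=False) for p in profiles]
    if len({v.shape for v in vecs}) != 1:
        raise ValidationError("profiles have incompatible shapes")
    mat = np.vstack(vecs)
    defined = ~np.isnan(mat).any(axis=0)
    mat = mat[:, defined]
    if center:
        mat = mat - mat.mean(axis=1, keepdims=True)
    diff = mat[:, None, :] - mat[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def pcoa(distance_matrix: np.ndarray, k: int = 2, ids: list[str] | None = None):
    """Classical principal-coordinates embedding of a distance matrix.

    Eigendecomposition of the double-centered squared-distance (Gower) matrix;
    coordinates are ordered by decreasing eigenvalue. Returns
    ``(coordinates, eigenvalues)`` where coordinates is an n x k DataFrame.
    For a Euclidean-embeddable matrix and k = rank, pairwise embedded
    distances reproduce the input exactly (up to numerical tolerance).
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValidationError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    if ids is None:
        ids = [f"p{i}" for i in range(n)]
    res = _skbio_pcoa(DistanceMatrix(d, ids=ids), method="eigh", number_of_dimensions=0)
    coords = res.samples.iloc[:, : min(k, res.samples.shape[1])].copy()
    coords.index = list(ids)
    if coords.shape[1] < k:  # pad degenerate embeddings (e.g. identical points)
        for j in range(coords.shape[1], k):
            coords[f"PC{j + 1}"] = 0.0
    eigvals = res.eigvals.to_numpy()
    return coords, eigvals
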