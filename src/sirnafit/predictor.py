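"""Cell-count predictors from siRNA guide sequence.

Two complementary models, trained on screen z-scores:

* a **positional linear model** — ordinary least squares of the phenotype on
  one-hot positional nucleotide indicators under sum-to-zero contrasts, so
  each position contributes four weights that sum to zero and are directly
  comparable to the positional phenotype profile;
* a **seed model** — the average phenotype of all training oligos sharing the
  same 7-mer seed (guide positions 2-8), capturing miRNA-like off-target
  effects that the strictly additive positional model cannot.

Their predictions are combined linearly; the mixing weight is chosen by
scanning a grid against held-out data (Pearson correlation). "Accuracy" is
reported as 100 x Pearson r between observed and predicted z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ScreenDataset, ValidationError, seed_of
from .profiles import ALPHABET, _sequence_matrix

DEFAULT_WEIGHT_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10))


@dataclass
class PositionalLinearModel:
    """Intercept + one weight per (position, nucleotide), sum-to-zero per position.

    ``degenerate`` lists (position, nucleotide) cells that were unidentifiable
    during fitting (nucleotide absent at that position); their weight is 0.
    """

    intercept: float
    weights: pd.DataFrame  # index A/C/G/T, columns = positions_used (1-based)
    degenerate: list = field(default_factory=list)

    @property
    def positions_used(self) -> list[int]:
        return [int(p) for p in self.weights.columns]

    def predict(self, guide_seq: str) -> float:
        return float(self.predict_many([guide_seq])[0])

    def predict_many(self, sequences: list[str]) -> np.ndarray:
        """Vectorized prediction: intercept + sum of positional weights.

        Positions beyond an oligo's length contribute nothing; a sequence
        shorter than the smallest modeled position is an error.
        """
        positions = self.positions_used
        if min(len(s) for s in sequences) < min(positions):
            raise ValidationError(
                f"sequence shorter than the smallest modeled position {min(positions)}"
            )
        codes, _ = _sequence_matrix(sequences)
        w = self.weights.to_numpy()  # 4 x P
        out = np.full(len(sequences), self.intercept, dtype=float)
        for j, p in enumerate(positions):
            if p - 1 >= codes.shape[1]:
                continue
            col = codes[:, p - 1]
            covered = col >= 0
            out[covered] += w[col[covered], j]
        return out

    def to_dict(self) -> dict:
        return {
            "kind": "positional_linear",
            "intercept": self.intercept,
            "positions": self.positions_used,
            "weights": {nt: self.weights.loc[nt].tolist() for nt in ALPHABET},
            "degenerate": [[int(p), nt] for p, nt in self.degenerate],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PositionalLinearModel":
        positions = d["positions"]
        weights = pd.DataFrame(
            [d["weights"][nt] for nt in ALPHABET], index=list(ALPHABET), columns=positions
        )
        return cls(
            intercept=float(d["intercept"]),
            weights=weights,
            degenerate=[(int(p), nt) for p, nt in d.get("degenerate", [])],
        )


@dataclass
class SeedModel:
    """Mean training phenotype per 7-mer seed; unseen seeds predict 0.

    0 is the screening-background mean on the z scale — the model abstains
    rather than extrapolates for seeds it has never observed.
    """

    table: dict  # seed -> (mean phenotype, count)
    min_count: int = 2
    default_prediction: float = 0.0

    def predict(self, guide_seq: str) -> tuple[float, bool]:
        entry = self.table.get(seed_of(guide_seq))
        if entry is None:
            return self.default_prediction, False
        return entry[0], True

    def predict_many(self, sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
        preds = np.empty(len(sequences))
        seen = np.empty(len(sequences), dtype=bool)
        for i, s in enumerate(sequences):
            preds[i], seen[i] = self.predict(s)
        return preds, seen

    def to_dict(self) -> dict:
        return {
            "kind": "seed",
            "min_count": self.min_count,
            "default_prediction": self.default_prediction,
            "table": {k: [v[0], int(v[1])] for k, v in self.table.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SeedModel":
        return cls(
            table={k: (float(m), int(n)) for k, (m, n) in d["table"].items()},
            min_count=int(d["min_count"]),
            default_prediction=float(d["default_prediction"]),
        )


@dataclass
class CombinedModel:
    """Weighted linear combination of the positional and seed models."""

    linear: PositionalLinearModel
    seed: SeedModel
    weight_linear: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.weight_linear <= 1.0:
            raise ValidationError("weight_linear must lie in [0, 1]")

    def predict(self, guide_seq: str) -> float:
        lin = self.linear.predict(guide_seq)
        sd, _ = self.seed.predict(guide_seq)
        return self.weight_linear * lin + (1.0 - self.weight_linear) * sd

    def predict_many(self, sequences: list[str]) -> np.ndarray:
        lin = self.linear.predict_many(sequences)
        sd, _ = self.seed.predict_many(sequences)
        return self.weight_linear * lin + (1.0 - self.weight_linear) * sd

    def to_dict(self) -> dict:
        return {
            "kind": "combined",
            "weight_linear": self.weight_linear,
            "linear": self.linear.to_dict(),
            "seed": self.seed.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CombinedModel":
        return cls(
            linear=PositionalLinearModel.from_dict(d["linear"]),
            seed=SeedModel.from_dict(d["seed"]),
            weight_linear=float(d["weight_linear"]),
        )


@dataclass
class EvaluationReport:
    pearson_r: float
    n: int
    accuracy_percent: float
    rmse: float


def split_dataset(
    dataset: ScreenDataset, train_fraction: float, rng_seed: int
) -> tuple[ScreenDataset, ScreenDataset]:
    """Disjoint, exhaustive, seed-reproducible train/test split by oligo."""
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(dataset))
    n_train = int(round(train_fraction * len(dataset)))
    return dataset.subset(perm[:n_train].tolist()), dataset.subset(perm[n_train:].tolist())


def _position_design(
    codes: np.ndarray, positions: list[int], reference: str | None
) -> tuple[np.ndarray, list[tuple[int, list[str], str]], list[tuple[int, str]]]:
    """Sum-contrast design matrix for the positional model.

    Per position p with present nucleotides S (|S| = m), emits m-1 columns
    x_nt = 1[nt at p] - 1[ref at p]; the reference weight is recovered as
    minus the sum. Oligos not covering p contribute zero to its columns.
    Returns (X, layout, degenerate) where layout records, per position, the
    encoded nucleotides and the reference.
    """
    cols = []
    layout = []
    degenerate: list[tuple[int, str]] = []
    for p in positions:
        col = codes[:, p - 1]
        present = [nt for k, nt in enumerate(ALPHABET) if (col == k).any()]
        absent = [nt for nt in ALPHABET if nt not in present]
        degenerate.extend((p, nt) for nt in absent)
        if len(present) <= 1:
            # no contrast is identifiable at this position
            degenerate.extend((p, nt) for nt in present)
            layout.append((p, [], ""))
            continue
        ref = reference if (reference in present) else present[-1]
        encoded = [nt for nt in present if nt != ref]
        refmask = (col == ALPHABET.index(ref)).astype(float)
        for nt in encoded:
            cols.append((col == ALPHABET.index(nt)).astype(float) - refmask)
        layout.append((p, encoded, ref))
    X = np.column_stack(cols) if cols else np.empty((codes.shape[0], 0))
    return X, layout, degenerate


def fit_positional_model(
    train: ScreenDataset,
    positions: list[int] | None = None,
    reference: str | None = None,
) -> PositionalLinearModel:
    """OLS fit of phenotype on positional nucleotide indicators.

    ``positions`` defaults to 2..L (position 1 is excluded, mirroring its
    technical design bias in commercial libraries). ``reference`` picks the
    contrast reference nucleotide; predictions are invariant to this choice.
    Unidentifiable weights (nucleotide absent at a position) are set to 0 and
    reported in ``model.degenerate``.
    """
    if len(train) == 0:
        raise ValidationError("cannot fit on an empty dataset")
    codes, lengths = _sequence_matrix(train.sequences())
    lmax = codes.shape[1]
    if positions is None:
        positions = list(range(2, lmax + 1))
    if min(positions) < 1 or max(positions) > lmax:
        raise ValidationError("requested positions outside the library's length range")
    z = train.phenotypes().to_numpy(dtype=float)

    X, layout, degenerate = _position_design(codes, positions, reference)
    Xi = np.column_stack([np.ones(len(z)), X])
    beta, *_ = np.linalg.lstsq(Xi, z, rcond=None)

    weights = pd.DataFrame(0.0, index=list(ALPHABET), columns=positions)
    j = 1
    for p, encoded, ref in layout:
        if not encoded:
            continue
        total = 0.0
        for nt in encoded:
            weights.loc[nt, p] = beta[j]
            total += beta[j]
            j += 1
        weights.loc[ref, p] = -total
    return PositionalLinearModel(
        intercept=float(beta[0]), weights=weights, degenerate=degenerate
    )


def predict_positional(model: PositionalLinearModel, guide_seq: str) -> float:
    return model.predict(guide_seq)


def fit_seed_model(train: ScreenDataset, min_count: int = 2) -> SeedModel:
    """Store the mean training phenotype of every seed group with count >= min_count."""
    df = train.to_frame()
    if len(df) == 0:
        return SeedModel(table={}, min_count=min_count)
    df["_seed"] = [seed_of(s) for s in df["guide_seq"]]
    g = df.groupby("_seed")["phenotype"].agg(["mean", "size"])
    g = g[g["size"] >= min_count]
    table = {seed: (float(row["mean"]), int(row["size"])) for seed, row in g.iterrows()}
    return SeedModel(table=table, min_count=min_count)


def predict_seed(model: SeedModel, guide_seq: str) -> tuple[float, bool]:
    return model.predict(guide_seq)


def predict_combined(model: CombinedModel, guide_seq: str) -> float:
    return model.predict(guide_seq)


def evaluate_predictions(observed, predicted) -> EvaluationReport:
    """Pearson r (and 100r as percent accuracy) plus RMSE of predictions."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValidationError("observed and predicted must have equal length")
    if obs.size < 3:
        raise ValidationError("need at least 3 paired values")
    if obs.std() == 0 or pred.std() == 0:
        raise ValidationError("zero variance in observed or predicted values")
    r = float(stats.pearsonr(obs, pred)[0])
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return EvaluationReport(pearson_r=r, n=obs.size, accuracy_percent=100.0 * r, rmse=rmse)


def scan_combination_weight(
    linear: PositionalLinearModel,
    seed: SeedModel,
    validation: ScreenDataset,
    grid=DEFAULT_WEIGHT_GRID,
) -> tuple[float, pd.DataFrame]:
    """Find the linear-model weight maximizing held-out Pearson correlation.

    Evaluates ``w * linear + (1-w) * seed`` for each grid weight against the
    validation phenotypes. Ties break toward the smaller weight. Returns
    ``(best_weight, curve)`` with the full (weight, pearson_r) curve.
    """
    if len(validation) == 0:
        raise ValidationError("empty validation dataset")
    obs = validation.phenotypes().to_numpy(dtype=float)
    if obs.std() == 0:
        raise ValidationError("validation phenotypes are constant")
    seqs = validation.sequences()
    lin_pred = linear.predict_many(seqs)
    seed_pred, _ = seed.predict_many(seqs)
    if lin_pred.std() == 0 and seed_pred.std() == 0:
        raise ValidationError("both models predict constants on the validation set")

    rows = []
    # An uninformative submodel (constant output) makes every interior weight
    # a rescaling of the other model's predictions: correlation is then flat
    # across the grid and the argmax is numerical noise. Short-circuit to the
    # informative model's endpoint.
    forced = None
    if seed_pred.std() == 0:
        forced = max(float(g) for g in grid)
    elif lin_pred.std() == 0:
        forced = min(float(g) for g in grid)
    best_w, best_r = None, -np.inf
    for w in sorted(float(g) for g in grid):
        combined = w * lin_pred + (1.0 - w) * seed_pred
        r = -np.inf if combined.std() == 0 else float(stats.pearsonr(obs, combined)[0])
        rows.append((w, r))
        if r > best_r:  # strict: ties keep the smaller weight
            best_w, best_r = w, r
    if best_w is None or not np.isfinite(best_r):
        raise ValidationError("no grid weight produced a non-degenerate prediction")
    if forced is not None:
        best_w = forced
    return best_w, pd.DataFrame(rows, columns=["weight", "pearson_r"])
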