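"""Model-driven design of novel, non-targeting siRNA sequences.

Three design classes mirror the validation experiment: *growth_restricting*
(tilt sampling toward cell-count-reducing nucleotides), *non_growth_restricting*
(tilt toward cell-count-increasing nucleotides), and *random_background*
(sample from the library's per-position nucleotide frequencies alone).

Sampling kernel: at each position, nucleotide probabilities are proportional
to ``background * exp(-w/T)`` (growth-restricting), ``background * exp(+w/T)``
(non-growth-restricting) or ``background`` alone, where ``w`` is the positional
linear-model weight and ``T`` a temperature. ``T -> inf`` recovers pure
background sampling in every class; ``T -> 0`` picks the per-position
argmin/argmax weight. A ``neutral`` variant (tilt toward small ``|w|``)
is available for designs meant to leave cell counts untouched rather than
to raise them.

Avoiding previously observed sequences or seeds is handled by rejection
sampling against an exclusion set; genome-scale on-target screening of the
designed oligos is intentionally out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError, seed_of
from .profiles import ALPHABET, FrequencyProfile
from .predictor import PositionalLinearModel

DESIGN_CLASSES = ("growth_restricting", "non_growth_restricting", "random_background")
_TILT_SIGN = {"growth_restricting": -1.0, "non_growth_restricting": +1.0, "random_background": 0.0}

MAX_ATTEMPTS_PER_OLIGO = 1000


class DesignError(ValidationError):
    """Design constraints are infeasible (rejection cap exceeded)."""


@dataclass
class DesignSpec:
    """What to design: class, count, length, sampling temperature, background,
    and sequences/seeds that must not be reproduced."""

    design_class: str
    n: int
    background: FrequencyProfile
    length: int = 19
    temperature: float = 0.05
    exclusion_set: set = field(default_factory=set)
    neutral: bool = False  # with non_growth_restricting: favor |w| ~ 0 instead of +w

    def __post_init__(self):
        if self.design_class not in DESIGN_CLASSES:
            raise ValidationError(
                f"unknown design class {self.design_class!r}; expected one of {DESIGN_CLASSES}"
            )
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if len(self.background.positions) < self.length:
            raise ValidationError(
                "background profile does not cover the requested design length"
            )


@dataclass
class DesignedOligo:
    sequence: str
    predicted_z: float
    design_class: str


def _position_probs(
    model: PositionalLinearModel, spec: DesignSpec
) -> np.ndarray:
    """Per-position sampling distribution (length x 4), exponentially tilted."""
    sign = _TILT_SIGN[spec.design_class]
    probs = np.empty((spec.length, 4))
    w = model.weights
    for p in range(1, spec.length + 1):
        bg = spec.background.freqs.loc[list(ALPHABET), p].to_numpy(dtype=float)
        if p in w.columns:
            wp = w.loc[list(ALPHABET), p].to_numpy(dtype=float)
        else:
            wp = np.zeros(4)  # positions outside the model (e.g. position 1)
        if spec.neutral and spec.design_class == "non_growth_restricting":
            tilt = np.exp(-np.abs(wp) / spec.temperature)
        else:
            tilt = np.exp(sign * wp / spec.temperature)
        unnorm = bg * tilt
        if unnorm.sum() == 0:
            raise DesignError(f"no admissible nucleotide at position {p}")
        probs[p - 1] = unnorm / unnorm.sum()
    return probs


def design_oligos(
    model: PositionalLinearModel,
    spec: DesignSpec,
    rng_seed: int,
) -> list[DesignedOligo]:
    """Sample ``spec.n`` novel sequences position-by-position.

    Each position's nucleotide is drawn independently from the tilted
    background distribution. Sequences whose full sequence or seed appears
    in ``spec.exclusion_set`` are rejected and resampled (cap 1000 attempts
    per oligo, then :class:`DesignError`). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(rng_seed)
    probs = _position_probs(model, spec)
    exclusion = set(spec.exclusion_set)
    emitted: set[str] = set()
    out: list[DesignedOligo] = []
    nts = np.array(list(ALPHABET))
    for _ in range(spec.n):
        for attempt in range(MAX_ATTEMPTS_PER_OLIGO):
            draw = [nts[rng.choice(4, p=probs[p])] for p in range(spec.length)]
            seq = "".join(draw)
            if seq in exclusion or seq in emitted:
                continue
            if len(seq) >= 8 and seed_of(seq) in exclusion:
                continue
            break
        else:
            raise DesignError(
                f"could not sample an admissible {spec.design_class} oligo in "
                f"{MAX_ATTEMPTS_PER_OLIGO} attempts: exclusion constraints infeasible"
            )
        emitted.add(seq)
        out.append(
            DesignedOligo(
                sequence=seq,
                predicted_z=model.predict(seq),
                design_class=spec.design_class,
            )
        )
    return out


def score_designs(
    designs: list[DesignedOligo],
    realized: dict | list | np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-class summary of predicted (and optionally realized) phenotypes.

    ``realized`` maps sequence -> observed z (dict) or is an array aligned
    with ``designs``. Returns ``(table, pearson_r)`` where r is the
    predicted-vs-realized correlation (NaN when realized is absent).
    """
    if not designs:
        raise ValidationError("no designs to score")
    classes = {d.design_class for d in designs}
    unknown = classes - set(DESIGN_CLASSES)
    if unknown:
        raise ValidationError(f"unknown design class labels: {sorted(unknown)}")

    df = pd.DataFrame(
        {
            "design_class": [d.design_class for d in designs],
            "predicted_z": [d.predicted_z for d in designs],
        }
    )
    if realized is not None:
        if isinstance(realized, dict):
            df["realized_z"] = [realized[d.sequence] for d in designs]
        else:
            arr = np.asarray(realized, dtype=float)
            if arr.shape[0] != len(designs):
                raise ValidationError("realized values must align with designs")
            df["realized_z"] = arr

    agg_cols = {"predicted_z": ["size", "mean", "std"]}
    if "realized_z" in df:
        agg_cols["realized_z"] = ["mean", "std"]
    table = df.groupby("design_class").agg(agg_cols)
    table.columns = ["_".join(c).replace("predicted_z_size", "n") for c in table.columns]
    table = table.rename(columns={"predicted_z_size": "n"})
    table = table.fillna({c: 0.0 for c in table.columns if c.endswith("_std")})

    r = float("nan")
    if "realized_z" in df and len(df) >= 3:
        if df["predicted_z"].std() > 0 and df["realized_z"].std() > 0:
            r = float(stats.pearsonr(df["predicted_z"], df["realized_z"])[0])
    return table, r
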