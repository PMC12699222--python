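"""Trial-sequence generation for the volatile motor-cueing (Posner) task.

The task is a centrally presented motor-cueing paradigm: on each trial a cue
indicates the probable response hand, and after a jittered stimulus onset
asynchrony a target shape appears that requires a left- or right-hand button
press.  Cue predictability (the proportion of valid cues) switches between
blocks among roughly 50, 70 and 90 %, and every simulated participant sees the
same sequence — the standard constant-input design for models that infer
conditional probabilities from a time series.

Validity is allocated by exact count (``round(p_valid * length)`` valid trials
per block, order shuffled by the seed) rather than by Bernoulli draws, so the
realized contingencies are controlled and testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BlockSpec",
    "CANONICAL_BLOCKS",
    "CANONICAL_SEED",
    "generate_trial_sequence",
    "generate_practice_sequence",
    "assign_timing",
]

#: Timing constants (ms).
CUE_DURATION_MS = 400.0
TARGET_DURATION_MS = 400.0
SOA_RANGE_MS = (1000.0, 1288.0)
ITI_RANGE_MS = (2012.0, 2300.0)

#: Seed that defines the fixed "published-like" sequence shared across
#: simulated participants.
CANONICAL_SEED = 20211443

#: Default target-shape -> response-hand mapping (counterbalanced across real
#: participants; here a config choice).
DEFAULT_SHAPE_FOR_HAND = {"right": "square", "left": "triangle"}


@dataclass(frozen=True)
class BlockSpec:
    """One block of trials at a constant latent cue predictability."""

    length: int
    p_valid: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"block length must be >= 1, got {self.length}")
        if not 0.0 <= self.p_valid <= 1.0:
            raise ValueError(f"p_valid must be in [0, 1], got {self.p_valid}")


#: Canonical main-task schedule: 6 blocks alternating among the three
#: predictability levels, 284 trials in total.  Multiple switches are required
#: for volatility inference to be identifiable.
CANONICAL_BLOCKS: tuple[BlockSpec, ...] = (
    BlockSpec(48, 0.5),
    BlockSpec(46, 0.9),
    BlockSpec(48, 0.7),
    BlockSpec(46, 0.9),
    BlockSpec(48, 0.5),
    BlockSpec(48, 0.7),
)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _balanced_sides(n: int, rng: np.random.Generator) -> np.ndarray:
    """n cue sides, balanced left/right up to rounding, shuffled."""
    n_left = n // 2
    sides = np.array(["left"] * n_left + ["right"] * (n - n_left), dtype=object)
    rng.shuffle(sides)
    return sides


def generate_trial_sequence(
    blocks=CANONICAL_BLOCKS,
    seed: int = CANONICAL_SEED,
    shape_for_hand: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Generate the main-task trial table.

    Per block exactly ``round(length * p_valid)`` trials are valid (round
    half-up), with the order shuffled by ``seed``; cue sides are balanced
    left/right within block up to rounding.  The sequence is a pure function
    of ``(blocks, seed)``.

    Returns a DataFrame with columns ``trial_index`` (1-based), ``cue_side``,
    ``target_shape``, ``required_hand``, ``validity`` (1 = valid; this is the
    binary input u(t) the observer filters), ``block_p_valid``,
    ``cue_duration_ms`` and ``target_duration_ms``.  Timing jitter columns are
    added by :func:`assign_timing`.
    """
    blocks = [b if isinstance(b, BlockSpec) else BlockSpec(*b) for b in blocks]
    if not blocks:
        raise ValueError("blocks list must be non-empty")
    shape_for_hand = dict(shape_for_hand or DEFAULT_SHAPE_FOR_HAND)

    rng = np.random.default_rng(seed)
    rows = []
    for block in blocks:
        n_valid = _round_half_up(block.length * block.p_valid)
        validity = np.zeros(block.length, dtype=int)
        validity[:n_valid] = 1
        rng.shuffle(validity)
        sides = _balanced_sides(block.length, rng)
        for v, side in zip(validity, sides):
            other = "right" if side == "left" else "left"
            hand = side if v else other
            rows.append(
                {
                    "cue_side": side,
                    "target_shape": shape_for_hand[hand],
                    "required_hand": hand,
                    "validity": int(v),
                    "block_p_valid": block.p_valid,
                }
            )
    table = pd.DataFrame(rows)
    table.insert(0, "trial_index", np.arange(1, len(table) + 1))
    table["cue_duration_ms"] = CUE_DURATION_MS
    table["target_duration_ms"] = TARGET_DURATION_MS
    return table


def generate_practice_sequence(seed: int = CANONICAL_SEED) -> pd.DataFrame:
    """Practice block: 54 trials at a constant 80 % cue predictability."""
    return generate_trial_sequence([BlockSpec(54, 0.8)], seed=seed)


def assign_timing(
    sequence: pd.DataFrame, seed: int = CANONICAL_SEED, jitter: bool = True
) -> pd.DataFrame:
    """Attach per-trial SOA and inter-trial-interval jitter.

    SOA is uniform on [1000, 1288] ms and the ITI uniform on [2012, 2300] ms.
    With ``jitter=False`` both collapse to their midpoints (1144 / 2156 ms).
    """
    if len(sequence) == 0:
        raise ValueError("sequence has no rows")
    out = sequence.copy()
    if jitter:
        rng = np.random.default_rng(seed)
        out["soa_ms"] = rng.uniform(*SOA_RANGE_MS, size=len(out))
        out["iti_ms"] = rng.uniform(*ITI_RANGE_MS, size=len(out))
    else:
        out["soa_ms"] = float(np.mean(SOA_RANGE_MS))
        out["iti_ms"] = float(np.mean(ITI_RANGE_MS))
    return out
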