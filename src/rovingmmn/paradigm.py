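"""Roving-oddball sequence generation.

A block is a fixed-length sequence of tones presented at a constant
onset-to-onset interval (SOA). Tones come in trains sharing one F0; at random
points the F0 jumps to a different value on the grid, and the first tone after
the jump is the (first-order) deviant, becoming the new standard after a few
repetitions. Train lengths are drawn from 3-11 with lengths 3-7 four times as
probable as 8-11. The first tones of a block and the first three tones of
every non-initial train carry deviant-order labels; tones from position 4
onward are standards; the first five tones of a block are excluded from
analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import DEFAULT_F0_GRID

__all__ = [
    "ParadigmConfig",
    "draw_train_length",
    "draw_next_f0",
    "generate_block",
    "block_duration",
    "train_length_probs",
    "SequentialPatternIds",
]


@dataclass(frozen=True)
class ParadigmConfig:
    soa: float = 0.600  # s, onset-to-onset
    block_len: int = 600
    train_min: int = 3
    train_max: int = 11
    short_max: int = 7  # lengths train_min..short_max get short_weight
    short_weight: float = 4.0
    long_weight: float = 1.0
    f0_grid: tuple[float, ...] = DEFAULT_F0_GRID
    n_blocks_per_condition: int = 2
    block_initial_exclusion: int = 5
    changing_pattern_per: str = "sound"  # or "train"

    def __post_init__(self) -> None:
        if self.short_weight <= 0 or self.long_weight <= 0:
            raise ValueError("weights must be positive")
        if self.block_len < self.train_max:
            raise ValueError("block_len must cover at least one train")
        if self.changing_pattern_per not in ("sound", "train"):
            raise ValueError("changing_pattern_per must be 'sound' or 'train'")


def train_length_probs(cfg: ParadigmConfig) -> tuple[np.ndarray, np.ndarray]:
    """(lengths, probabilities) of the train-length distribution."""
    lengths = np.arange(cfg.train_min, cfg.train_max + 1)
    weights = np.where(lengths <= cfg.short_max, cfg.short_weight, cfg.long_weight)
    return lengths, weights / weights.sum()


def draw_train_length(rng: np.random.Generator, cfg: ParadigmConfig) -> int:
    lengths, probs = train_length_probs(cfg)
    return int(rng.choice(lengths, p=probs))


def draw_next_f0(rng: np.random.Generator, current: float, cfg: ParadigmConfig) -> float:
    """Uniform draw over grid values different from ``current``."""
    others = [f for f in cfg.f0_grid if f != current]
    if not others:
        raise ValueError("f0 grid has no alternative values")
    return float(others[rng.integers(len(others))])


class SequentialPatternIds:
    """Default pattern source: opaque sequential jitter-pattern ids."""

    def __init__(self, prefix: str = "jp") -> None:
        self._counter = itertools.count()
        self.prefix = prefix

    def __call__(self, rng: np.random.Generator) -> str:
        return f"{self.prefix}{next(self._counter):05d}"


def generate_block(
    condition: str,
    rng: np.random.Generator,
    cfg: ParadigmConfig | None = None,
    pattern_source=None,
) -> pd.DataFrame:
    """One block's event table.

    Pattern assignment: harmonic blocks carry no pattern; inharmonic blocks
    use a single pattern throughout; changing blocks draw a fresh pattern per
    sound (default) or per train (config switch). The final train is truncated
    so the block has exactly ``block_len`` events.
    """
    cfg = cfg or ParadigmConfig()
    if condition not in ("harmonic", "inharmonic", "changing"):
        raise ValueError(f"unknown condition {condition!r}")
    if pattern_source is None:
        pattern_source = SequentialPatternIds()

    block_pattern = None
    if condition == "inharmonic":
        block_pattern = pattern_source(rng)

    rows: list[tuple] = []
    f0 = float(cfg.f0_grid[rng.integers(len(cfg.f0_grid))])
    prev_f0 = None
    train_index = 0
    while len(rows) < cfg.block_len:
        length = draw_train_length(rng, cfg)
        shift = None if prev_f0 is None else f0 - prev_f0
        train_pattern = None
        if condition == "changing" and cfg.changing_pattern_per == "train":
            train_pattern = pattern_source(rng)
        for pos in range(1, length + 1):
            idx = len(rows)
            if idx >= cfg.block_len:
                break
            if condition == "harmonic":
                pattern_id = None
            elif condition == "inharmonic":
                pattern_id = block_pattern
            elif cfg.changing_pattern_per == "sound":
                pattern_id = pattern_source(rng)
            else:
                pattern_id = train_pattern
            deviant_order = pos if (train_index > 0 and pos <= 3) else None
            if idx < cfg.block_initial_exclusion:
                role = "excluded"
            elif deviant_order is not None:
                role = "deviant"
            elif pos >= 4:
                role = "standard"
            else:  # positions 1-3 of the block-initial train, always idx < 5
                role = "excluded"
            rows.append(
                (
                    idx,
                    idx * cfg.soa,
                    f0,
                    condition,
                    pattern_id,
                    train_index,
                    pos,
                    deviant_order,
                    role,
                    shift,
                )
            )
        prev_f0 = f0
        f0 = draw_next_f0(rng, f0, cfg)
        train_index += 1

    table = pd.DataFrame(
        rows,
        columns=[
            "index",
            "onset",
            "f0",
            "condition",
            "pattern_id",
            "train_index",
            "position_in_train",
            "deviant_order",
            "role",
            "shift_hz",
        ],
    )
    table["deviant_order"] = table["deviant_order"].astype("Int64")
    return table


def block_duration(table: pd.DataFrame, cfg: ParadigmConfig | None = None) -> float:
    """Block duration in seconds under the onset-to-onset SOA reading."""
    cfg = cfg or ParadigmConfig()
    return len(table) * cfg.soa
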