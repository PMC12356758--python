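"""Mapping abstract IE levels to concrete stimuli.

Perceptual task: two 15 x 20 grids of black/white squares.  The IE level sets
the between-grid difference in white squares while the total number of white
squares on screen stays constant.  Value task: pairs of rated food items whose
signed rating difference falls in one of nine equal-width bins matched to the
nine IE levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequences import as_rng

__all__ = [
    "GridStimulusPair",
    "ValuePairSpec",
    "UnsatisfiableDesignError",
    "map_ie_to_grid",
    "exclude_extreme_items",
    "build_value_pairs",
    "rescale_to_unit",
    "PERCEPTUAL_SCALE_ENDPOINT",
]

GRID_ROWS = 15
GRID_COLS = 20
GRID_SQUARES = GRID_ROWS * GRID_COLS  # 300
#: white squares moved between the grids per |IE| level of 0.1 (7% of 300)
SQUARES_PER_LEVEL = round(0.07 * GRID_SQUARES)  # 21
#: slider endpoints of the perceptual task mean a 60% white-square difference
PERCEPTUAL_SCALE_ENDPOINT = 60.0


class UnsatisfiableDesignError(ValueError):
    """A stimulus design constraint cannot be satisfied with these inputs."""


@dataclass(frozen=True)
class GridStimulusPair:
    left_white: int
    right_white: int
    n_squares: int = GRID_SQUARES
    rows: int = GRID_ROWS
    cols: int = GRID_COLS

    @property
    def percent_difference(self) -> float:
        """Signed white-square difference (right - left) as % of one grid."""
        return 100.0 * (self.right_white - self.left_white) / self.n_squares


@dataclass(frozen=True)
class ValuePairSpec:
    left_item: object
    right_item: object
    rating_diff: float  # right - left, rating units
    bin_index: int  # 1..9, matched to IE levels -0.4..+0.4


def map_ie_to_grid(ie_level: float) -> GridStimulusPair:
    """Grid pair for one IE level; positive IE makes the right grid whiter."""
    level = np.round(float(ie_level) * 10)
    if not np.isclose(level / 10.0, ie_level, atol=1e-9) or abs(level) > 4:
        raise ValueError(
            f"ie_level {ie_level!r} is not on the nine-level alphabet"
        )
    k = int(level)
    half = GRID_SQUARES // 2
    return GridStimulusPair(
        left_white=half - SQUARES_PER_LEVEL * k,
        right_white=half + SQUARES_PER_LEVEL * k,
    )


def exclude_extreme_items(ratings: pd.Series) -> pd.Series:
    """Drop the 5% lowest- and highest-rated items plus any rated 0 or 10.

    The tails are ``ceil(0.05 * n)`` items each, removed in rating order;
    items rated exactly 0 or 10 are removed regardless.
    """
    ratings = ratings.astype(float)
    n_tail = int(np.ceil(0.05 * len(ratings)))
    order = ratings.sort_values(kind="stable")
    drop = set(order.index[:n_tail]) | set(order.index[len(order) - n_tail:])
    drop |= set(ratings.index[(ratings == 0.0) | (ratings == 10.0)])
    return ratings.drop(index=list(drop))


def _bin_edges(diff_range: float, n_bins: int = 9) -> np.ndarray:
    return np.linspace(-diff_range, diff_range, n_bins + 1)


def assign_bin(rating_diff: float, edges: np.ndarray) -> int:
    """1-based bin of a signed rating difference; bins half-open, last closed."""
    idx = int(np.searchsorted(edges, rating_diff, side="right"))
    if rating_diff == edges[-1]:
        idx = len(edges) - 1
    if idx < 1 or idx > len(edges) - 1:
        raise ValueError(f"rating_diff {rating_diff} outside bin range")
    return idx


def build_value_pairs(ratings, block, rng_seed) -> list:
    """Draw food pairs matching each IE level of a block sequence.

    After excluding extreme items, all ordered pairs of the survivors are
    binned by signed rating difference into nine equal-width bins spanning
    the symmetric difference range, matched 1:1 to the IE levels.  Each
    sequence entry draws a pair from its bin, without replacement within
    the block while the bin lasts, falling back to replacement.

    Parameters
    ----------
    ratings : pd.Series or pd.DataFrame
        Item ratings 0-10; a DataFrame must have columns item, rating.
    block : BlockSequence
    rng_seed : int, SeedSequence or Generator
    """
    if isinstance(ratings, pd.DataFrame):
        ratings = ratings.set_index("item")["rating"]
    rng = as_rng(rng_seed)
    kept = exclude_extreme_items(ratings)
    if len(kept) < 2:
        raise UnsatisfiableDesignError("fewer than 2 items survive exclusion")
    diff_range = float(kept.max() - kept.min())
    if diff_range == 0:
        raise UnsatisfiableDesignError(
            "all surviving ratings identical: bins for nonzero IE levels "
            "(all but bin 5) are empty"
        )
    edges = _bin_edges(diff_range)

    items = kept.index.to_numpy()
    vals = kept.to_numpy()
    # ordered pairs, left != right
    li, ri = np.meshgrid(np.arange(len(items)), np.arange(len(items)),
                         indexing="ij")
    mask = li != ri
    li, ri = li[mask], ri[mask]
    diffs = vals[ri] - vals[li]
    bins = np.searchsorted(edges, diffs, side="right")
    bins[diffs == edges[-1]] = 9

    pools = {b: list(np.flatnonzero(bins == b)) for b in range(1, 10)}
    needed_levels = sorted({lv for trial in block.trials for lv in trial.ie})
    for lv in needed_levels:
        b = int(round(lv * 10)) + 5
        if not pools[b]:
            raise UnsatisfiableDesignError(
                f"bin {b} (IE level {lv:+.1f}) has no item pairs"
            )

    remaining = {b: list(rng.permutation(p)) for b, p in pools.items()}
    out = []
    for trial in block.trials:
        for lv in trial.ie:
            b = int(round(lv * 10)) + 5
            if remaining[b]:
                j = remaining[b].pop()
            else:  # bin exhausted within the block: sample with replacement
                j = int(rng.choice(pools[b]))
            out.append(ValuePairSpec(
                left_item=items[li[j]], right_item=items[ri[j]],
                rating_diff=float(diffs[j]), bin_index=int(bins[j]),
            ))
    return out


def rescale_to_unit(raw_value, task: str, scale_endpoint: float):
    """Rescale a task-native signed difference to the -1..+1 slider scale.

    ``scale_endpoint`` is 60 (% white-square difference) for the perceptual
    task and the rounded maximum rating difference for the value task.
    Values beyond the endpoints are clipped.
    """
    if task not in ("perceptual", "value"):
        raise ValueError(f"unknown task {task!r}")
    if scale_endpoint <= 0:
        raise ValueError(f"scale_endpoint must be > 0, got {scale_endpoint}")
    return np.clip(np.asarray(raw_value, dtype=float) / scale_endpoint,
                   -1.0, 1.0)[()]
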