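"""Deterministic Kennard–Stone calibration/test splitting.

Kennard–Stone greedily selects a calibration subset that spans the feature
space: it seeds with the pair of points at maximum Euclidean distance, then
repeatedly adds the point whose minimum distance to the already-selected set
is largest. The remainder forms the test set. The procedure is fully
deterministic; ties are broken toward the lowest row index.

Distances are computed on the unscaled (r, g, b) descriptors, pooled across
classes — the split is of the dataset as a whole, not stratified (a
stratified variant is not provided; an explicit calibration-size override
is).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Dataset


@dataclass(frozen=True)
class SplitResult:
    """Calibration/test index partition.

    ``calibration_indices`` are in Kennard–Stone selection order;
    ``test_indices`` preserve dataset order. Sorted views are provided for
    set-like use.
    """

    calibration_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    fraction: float

    def __post_init__(self) -> None:
        cal, test = set(self.calibration_indices), set(self.test_indices)
        if cal & test:
            raise ValueError("calibration and test indices overlap")
        n = len(self.calibration_indices) + len(self.test_indices)
        if cal | test != set(range(n)):
            raise ValueError("split does not cover 0..n-1 exactly")

    @property
    def calibration_sorted(self) -> tuple[int, ...]:
        return tuple(sorted(self.calibration_indices))

    @property
    def test_sorted(self) -> tuple[int, ...]:
        return tuple(sorted(self.test_indices))

    def to_rows(self, sample_ids: list[str]) -> list[tuple[str, str]]:
        """(sample_id, set) rows for the two-column split CSV."""
        assignment = {i: "cal" for i in self.calibration_indices}
        assignment.update({i: "test" for i in self.test_indices})
        return [(sample_ids[i], assignment[i]) for i in range(len(sample_ids))]


def kennard_stone(points: np.ndarray, k: int) -> list[int]:
    """Select ``k`` row indices by the Kennard–Stone algorithm.

    Returns indices in selection order. The first two are a maximum-distance
    pair (lower index first); each later pick maximizes the minimum distance
    to everything already selected, lowest index winning ties.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 2 or k > n:
        raise ValueError(f"k must satisfy 2 <= k <= n={n}, got {k}")

    # Pairwise squared distances; n is small (study designs are 55/150 rows).
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)

    flat = np.argmax(sq)  # argmax returns the first (lowest flat index) maximum
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    min_dist = np.minimum(sq[selected[0]], sq[selected[1]])

    while len(selected) < k:
        masked = np.where(in_set, -np.inf, min_dist)
        nxt = int(np.argmax(masked))  # ties -> lowest index
        selected.append(nxt)
        in_set[nxt] = True
        min_dist = np.minimum(min_dist, sq[nxt])
    return selected


def calibration_size(n: int, fraction: float) -> int:
    """round(fraction * n) with ties away from zero (so 38.5 -> 39)."""
    return int(math.floor(fraction * n + 0.5))


def split_dataset(
    ds: Dataset,
    fraction: float = 0.7,
    calibration_size_override: int | None = None,
) -> SplitResult:
    """Kennard–Stone split of a dataset's pooled feature matrix.

    The calibration set holds ``round(fraction * n)`` samples unless an
    explicit ``calibration_size_override`` is given.
    """
    n = len(ds)
    if calibration_size_override is not None:
        k = calibration_size_override
        if k > n:
            raise ValueError(f"override {k} exceeds dataset size {n}")
    else:
        if not (0.0 < fraction < 1.0):
            raise ValueError("fraction must lie in (0, 1)")
        k = calibration_size(n, fraction)
    if k < 2:
        raise ValueError(f"calibration size {k} too small (need >= 2)")

    cal = kennard_stone(ds.feature_matrix(), k)
    cal_set = set(cal)
    test = [i for i in range(n) if i not in cal_set]
    return SplitResult(
        calibration_indices=tuple(cal),
        test_indices=tuple(test),
        fraction=fraction,
    )


def write_split(split: SplitResult, sample_ids: list[str], path) -> None:
    """Write the split as a two-column CSV (sample_id, set in {cal, test})."""
    with open(path, "w") as fh:
        fh.write("sample_id,set\n")
        for sid, which in split.to_rows(sample_ids):
            fh.write(f"{sid},{which}\n")
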