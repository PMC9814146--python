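"""Map normalization, equilibrium-difference maps, datasets and synthetic counts.

The network never sees raw cross-sections.  Each map is normalized to unit
sum — which puts simulated and measured maps on a common scale and removes
any overall detection-efficiency factor — and the normalized map of the
equilibrium reference structure is subtracted.  The resulting difference map
integrates to zero and isolates the structure-dependent interference fringes
from the slowly varying atomic background.

A synthetic "experiment" is produced by drawing counts over the pixels of a
ground-truth map with Poisson statistics at a configurable total count,
standing in for reaction-microscope data.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .geometry import LabelScheme, MolecularStructure
from .scattering import DCSGrid, DCSMap, dcs_map, dcs_map_stack

__all__ = [
    "DiffMap",
    "Dataset",
    "CountsMap",
    "normalize_map",
    "difference_map",
    "assemble_dataset",
    "poissonize",
    "poisson_extrema",
    "counts_to_map",
    "save_dataset",
    "load_dataset",
]


def normalize_map(values: np.ndarray) -> np.ndarray:
    """Scale a map to unit sum.

    Scale-invariant (``normalize(c*M) == normalize(M)`` for c > 0), which is
    what makes experimental and simulated maps directly comparable.
    """
    values = np.asarray(values, dtype=float)
    total = values.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("map must have a positive total to be normalized")
    return values / total


@dataclass
class DiffMap:
    """A normalized map minus the normalized reference map; sums to zero."""

    grid: DCSGrid
    values: np.ndarray
    reference_name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match the grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("difference map values must be finite")


def difference_map(dcsmap: DCSMap, reference: DCSMap) -> DiffMap:
    """normalize(map) - normalize(reference) on a shared grid."""
    if dcsmap.grid != reference.grid:
        raise ValueError("map and reference are on different grids")
    return DiffMap(dcsmap.grid,
                   normalize_map(dcsmap.values) - normalize_map(reference.values),
                   reference_name=reference.structure_name)


@dataclass
class Dataset:
    """Difference-map images with label vectors and a train/val/test split.

    ``inputs`` has shape ``(n_samples,) + grid.shape``; label normalization
    statistics (per-dimension min/max) are computed from the training split
    only, so validation and test data never leak into the scaling.
    """

    grid: DCSGrid
    inputs: np.ndarray
    labels: np.ndarray
    scheme: LabelScheme | None
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    label_min: np.ndarray
    label_max: np.ndarray
    reference_name: str = ""

    def __post_init__(self):
        if len(self.inputs) != len(self.labels):
            raise ValueError("inputs and labels must have equal length")
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(np.unique(all_idx)) != len(all_idx) or len(all_idx) != len(self.inputs):
            raise ValueError("splits must be disjoint and cover every entry")

    @property
    def n_labels(self) -> int:
        return self.labels.shape[1]

    def split(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        idx = {"train": self.train_idx, "validation": self.val_idx,
               "test": self.test_idx}[name]
        return self.inputs[idx], self.labels[idx]


def assemble_dataset(database, reference: MolecularStructure, grid: DCSGrid,
                     model, fractions=(0.8, 0.1, 0.1), seed: int = 0,
                     scheme: LabelScheme | None = None,
                     compute_dtype=np.float32) -> Dataset:
    """Turn a (structure, label) database into a split difference-map dataset.

    Each entry's IAM map is normalized and differenced against the reference
    structure's map; entries are shuffled with ``seed`` and split per
    ``fractions`` (train, validation, test).  Deterministic under a fixed
    seed.  Maps are simulated in ``compute_dtype`` (single precision by
    default: the regressor consumes float32 images and the ~1e-7 relative
    rounding is negligible against any realistic counting noise).
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be three positive numbers summing to 1")
    structures = [s for s, _ in database]
    labels = np.asarray([v for _, v in database], dtype=float)
    n = len(structures)

    n_train = int(round(fr[0] * n))
    n_val = int(round(fr[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("database too small: a split would be empty")

    ref_map = normalize_map(dcs_map(reference, model, grid).values).astype(compute_dtype)
    stack = dcs_map_stack(structures, model, grid, dtype=compute_dtype)
    sums = stack.sum(axis=(1, 2), keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("encountered a non-positive map total")
    inputs = stack / sums - ref_map[None, :, :]

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = np.sort(order[:n_train])
    val_idx = np.sort(order[n_train:n_train + n_val])
    test_idx = np.sort(order[n_train + n_val:])

    lmin = labels[train_idx].min(axis=0)
    lmax = labels[train_idx].max(axis=0)
    return Dataset(grid, inputs, labels, scheme, train_idx, val_idx, test_idx,
                   lmin, lmax, reference_name=reference.name)


# ---------------------------------------------------------------------------
# Synthetic experiment: Poisson counting statistics
# ---------------------------------------------------------------------------

@dataclass
class CountsMap:
    """Integer detector counts on a DCS grid; ``counts.sum() == total_counts``."""

    grid: DCSGrid
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.grid.shape:
            raise ValueError("counts shape does not match the grid")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


def poissonize(dcsmap: DCSMap, total_counts: int, seed: int = 0) -> CountsMap:
    """Draw detector counts over the map's pixels at a given total count.

    Pixel expectations are ``normalize(map) * total_counts``; counts are
    drawn multinomially, i.e. as independent Poisson pixels conditioned on
    the exact total, so per-pixel statistics are Poissonian (variance equals
    the mean) whenever individual pixel fractions are small.  Deterministic
    under a fixed seed.
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    p = normalize_map(dcsmap.values).ravel()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(total_counts), p).reshape(dcsmap.grid.shape)
    return CountsMap(dcsmap.grid, counts)


def poisson_extrema(counts: CountsMap) -> tuple[DCSMap, DCSMap]:
    """One-standard-error envelope of a counts map.

    Poisson counting error per pixel is sqrt(n): the lower map is
    ``n - sqrt(n)`` clipped at zero, the upper ``n + sqrt(n)``.  These
    extremal maps bound the experimental statistical error and are pushed
    through the retrieval to propagate it into the structure.
    """
    c = counts.counts.astype(float)
    rt = np.sqrt(c)
    lower = DCSMap(counts.grid, np.clip(c - rt, 0.0, None), structure_name="lower")
    upper = DCSMap(counts.grid, c + rt, structure_name="upper")
    return lower, upper


def counts_to_map(counts: CountsMap) -> DCSMap:
    """View a counts map as an intensity map (for differencing/prediction)."""
    return DCSMap(counts.grid, counts.counts.astype(float), structure_name="counts")


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_dataset(dataset: Dataset, path) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("return_energies", data=dataset.grid.return_energies)
        h.create_dataset("rescattering_angles", data=dataset.grid.rescattering_angles)
        h.create_dataset("inputs", data=dataset.inputs)
        h.create_dataset("labels", data=dataset.labels)
        for name in ("train_idx", "val_idx", "test_idx", "label_min", "label_max"):
            h.create_dataset(name, data=getattr(dataset, name))
        h.attrs["reference_name"] = dataset.reference_name


def load_dataset(path) -> Dataset:
    with h5py.File(path, "r") as h:
        grid = DCSGrid(h["return_energies"][:], h["rescattering_angles"][:])
        return Dataset(grid, h["inputs"][:], h["labels"][:], None,
                       h["train_idx"][:], h["val_idx"][:], h["test_idx"][:],
                       h["label_min"][:], h["label_max"][:],
                       reference_name=str(h.attrs.get("reference_name", "")))
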