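"""Core data model for longitudinal compositional microbiome profiles.

The unit of analysis is one individual's time series of relative-abundance
vectors (a :class:`LongitudinalProfile`).  Every sample lives on the simplex:
non-negative entries summing to one.  Times are stored in days relative to
the individual's first sample.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SIMPLEX_ATOL",
    "OTHERS_LABEL",
    "CompositionVector",
    "LongitudinalProfile",
    "normalize",
    "select_top_taxa",
]

SIMPLEX_ATOL = 1e-9
OTHERS_LABEL = "others"


@dataclasses.dataclass(frozen=True)
class CompositionVector:
    """A single sample's relative-abundance vector on the simplex.

    Parameters
    ----------
    values
        Non-negative abundances summing to 1 (within ``SIMPLEX_ATOL``).
    taxa
        Optional taxon labels aligned to ``values``.
    """

    values: np.ndarray
    taxa: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("composition must be a 1-d vector")
        if np.any(values < -SIMPLEX_ATOL):
            raise ValueError("composition entries must be non-negative")
        total = float(values.sum())
        if not np.isfinite(total) or abs(total - 1.0) > SIMPLEX_ATOL:
            raise ValueError(f"composition must sum to 1 (got {total!r})")
        values = np.clip(values, 0.0, None)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        if self.taxa is not None:
            taxa = tuple(self.taxa)
            if len(taxa) != values.size:
                raise ValueError("taxa labels do not match vector length")
            object.__setattr__(self, "taxa", taxa)

    def __len__(self) -> int:
        return self.values.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def normalize(values: Iterable[float] | np.ndarray) -> CompositionVector:
    """Close a non-negative vector to the simplex (divide by its sum).

    Raises
    ------
    ValueError
        If any entry is negative or the vector has no positive entry.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("cannot normalize a vector with negative entries")
    total = arr.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero vector")
    return CompositionVector(arr / total)


@dataclasses.dataclass(frozen=True)
class LongitudinalProfile:
    """One individual's time-stamped compositional matrix.

    Attributes
    ----------
    individual_id
        Label of the individual.
    times
        Strictly increasing sample times, in days since the first sample.
    taxa
        Unique taxon labels; after :func:`select_top_taxa` the final label
        is the aggregated ``"others"`` category.
    abundances
        Matrix of shape ``(n_samples, n_taxa)``; each row on the simplex
        when ``simplex`` is True.
    dataset
        Cohort/data-set label used by cross-individual analyses.
    simplex
        When False, rows are unconstrained positive abundances.  This mode
        exists for analytic validation of the population-dynamics estimators
        on absolute abundances and is never produced by the I/O layer.
    """

    individual_id: str
    times: np.ndarray
    taxa: tuple[str, ...]
    abundances: np.ndarray
    dataset: str = "default"
    simplex: bool = True

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ab = np.asarray(self.abundances, dtype=float)
        if times.ndim != 1 or ab.ndim != 2:
            raise ValueError("times must be 1-d and abundances 2-d")
        if times.size < 2:
            raise ValueError("a profile needs at least 2 samples")
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        taxa = tuple(str(t) for t in self.taxa)
        if len(set(taxa)) != len(taxa):
            raise ValueError("taxa labels must be unique")
        if ab.shape != (times.size, len(taxa)):
            raise ValueError(
                f"abundance matrix shape {ab.shape} does not match "
                f"{times.size} samples x {len(taxa)} taxa"
            )
        if np.any(ab < -SIMPLEX_ATOL) or not np.all(np.isfinite(ab)):
            raise ValueError("abundances must be finite and non-negative")
        ab = np.clip(ab, 0.0, None)
        if self.simplex:
            sums = ab.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > SIMPLEX_ATOL):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"sample {bad} is not on the simplex (sum={sums[bad]!r})"
                )
        times.setflags(write=False)
        ab.setflags(write=False)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "abundances", ab)
        object.__setattr__(self, "taxa", taxa)

    # -- basic queries ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sample(self, index: int) -> CompositionVector:
        """The composition at sample ``index`` (supports negative indices)."""
        row = self.abundances[index]
        if self.simplex:
            return CompositionVector(row, taxa=self.taxa)
        return CompositionVector(row / row.sum(), taxa=self.taxa)

    def nearest_preceding(self, target_time: float) -> int:
        """Index of the latest sample strictly before ``target_time``."""
        idx = int(np.searchsorted(self.times, target_time, side="left")) - 1
        if idx < 0:
            raise ValueError(
                f"no sample precedes time {target_time} "
                f"(first sample at {self.times[0]})"
            )
        return idx

    # -- derived profiles ------------------------------------------------

    def subset(self, indices: Sequence[int]) -> "LongitudinalProfile":
        """Profile restricted to the given sample indices (sorted)."""
        idx = np.unique(np.asarray(indices, dtype=int))
        return dataclasses.replace(
            self, times=self.times[idx], abundances=self.abundances[idx]
        )

    def without_sample(self, index: int) -> "LongitudinalProfile":
        """Profile with one sample removed (leave-one-out helper)."""
        keep = np.ones(self.n_samples, dtype=bool)
        keep[index] = False
        return dataclasses.replace(
            self, times=self.times[keep], abundances=self.abundances[keep]
        )

    def to_dataframe(self):
        """Samples x taxa DataFrame indexed by time (days)."""
        import pandas as pd

        return pd.DataFrame(self.abundances, index=self.times, columns=list(self.taxa))


def select_top_taxa(
    profile: LongitudinalProfile,
    k: int = 30,
    others_label: str = OTHERS_LABEL,
) -> LongitudinalProfile:
    """Keep the ``k`` taxa with highest mean relative abundance, pool the rest.

    The remaining taxa are summed into a final ``others`` column, which is
    always present (zero if nothing was pooled) so that downstream methods
    see a fixed taxon set.  An existing ``others`` column never competes for
    a top-``k`` slot; its mass is folded into the new pooled column, which
    makes the operation idempotent for fixed ``k``.  Ties in mean abundance
    at the ``k``-th rank are broken lexicographically by taxon label.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    taxa = np.array(profile.taxa)
    candidate = taxa != others_label
    means = profile.abundances.mean(axis=0)
    cand_idx = np.flatnonzero(candidate)
    # stable order: descending mean, then label
    order = sorted(cand_idx, key=lambda i: (-means[i], taxa[i]))
    kept = order[: min(k, len(order))]
    pooled = [i for i in range(len(taxa)) if i not in set(kept)]
    new_ab = np.column_stack(
        [profile.abundances[:, kept],
         profile.abundances[:, pooled].sum(axis=1)
         if pooled else np.zeros(profile.n_samples)]
    )
    new_taxa = tuple(taxa[kept]) + (others_label,)
    return dataclasses.replace(profile, taxa=new_taxa, abundances=new_ab)
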