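"""Sample-to-group mapping with group weights.

The weights w_g are the probability a random observation is drawn from
group g under the chosen estimator.  The default is equal weighting
(w_g = 1/G), which makes every group contribute equally to the pooled
frequencies regardless of how many reads it was sequenced to — the
modification that removes read-depth imbalance between compartments.
Read-proportional weights (the unmodified estimator) are available for
comparison via :func:`phylodiv.partition.compute_branch_frequencies`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import UndefinedQuantityError, ValidationError

__all__ = ["Grouping"]


@dataclass(frozen=True)
class Grouping:
    """Maps samples to groups; carries the ordered group list and weights."""

    sample_to_group: Mapping[str, str]
    groups: tuple[str, ...]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        groups = tuple(self.groups)
        object.__setattr__(self, "groups", groups)
        if not groups:
            raise ValidationError("at least one group required")
        w = self.weights
        if w is None:
            w = np.full(len(groups), 1.0 / len(groups))
        w = np.asarray(w, dtype=float)
        if w.shape != (len(groups),):
            raise ValidationError("one weight per group required")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValidationError("group weights must be nonnegative and sum to 1")
        object.__setattr__(self, "weights", w)
        seen = set(self.sample_to_group.values())
        for g in groups:
            if g not in seen:
                raise ValidationError(f"group {g!r} has no samples")
        unknown = seen - set(groups)
        if unknown:
            raise ValidationError(f"samples mapped to undeclared groups: {sorted(unknown)}")

    @classmethod
    def from_mapping(
        cls,
        sample_to_group: Mapping[str, str],
        groups: tuple[str, ...] | None = None,
        weights: np.ndarray | None = None,
    ) -> "Grouping":
        if groups is None:
            groups = tuple(dict.fromkeys(sample_to_group.values()))
        return cls(dict(sample_to_group), tuple(groups), weights)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_index(self, group: str) -> int:
        return self.groups.index(group)

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.sample_to_group.items() if g == group]

    def entropy(self) -> float:
        """H(G) = -sum_g w_g ln w_g in nats; the ceiling for the
        phylogenetic mutual information and the turnover denominator."""
        w = self.weights[self.weights > 0]
        return float(-(w * np.log(w)).sum())

    def require_samples(self, samples) -> None:
        missing = [s for s in samples if s not in self.sample_to_group]
        if missing:
            raise ValidationError(f"samples not mapped to any group: {missing}")

    def subset(self, groups: tuple[str, ...]) -> "Grouping":
        """Restrict to the given groups (equal re-normalized weights)."""
        mapping = {s: g for s, g in self.sample_to_group.items() if g in groups}
        return Grouping.from_mapping(mapping, tuple(groups))
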