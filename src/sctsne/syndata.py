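"""Hierarchical Gaussian-mixture benchmark data.

Generates the 15-class synthetic benchmark used throughout the test suite: a
mixture of spherical unit-variance Gaussians in 50 dimensions, organised into
three *classes* of five *types* each.  Class means are shifted by 20 along
mutually orthogonal directions; type means within a class are additionally
shifted by 4 or 10 along directions orthogonal to each other and to the class
shifts.  The resulting data set has two levels of structure (macroscopic
classes, mesoscopic types) and is the standard stress test for whether an
embedding preserves geometry at both levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClassSpec", "MixtureSpec", "LabeledMatrix", "default_benchmark_spec", "generate"]


@dataclass(frozen=True)
class ClassSpec:
    """One class of the mixture: ``n_types`` Gaussians sharing a class shift.

    Parameters
    ----------
    between_shift
        Magnitude of the class-mean shift along this class's own orthogonal
        direction.
    within_shift
        Magnitude of each type-mean shift within the class, along directions
        orthogonal to every class direction and to each other.
    n_types
        Number of Gaussian components (types) in the class.
    points_per_type
        Sample size drawn from each component.
    """

    between_shift: float
    within_shift: float
    n_types: int
    points_per_type: int


@dataclass(frozen=True)
class MixtureSpec:
    """Full specification of a hierarchical Gaussian mixture."""

    dimension: int = 50
    classes: tuple[ClassSpec, ...] = ()
    seed: int = 42
    shuffle: bool = False

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_types(self) -> int:
        return sum(c.n_types for c in self.classes)

    @property
    def n_points(self) -> int:
        return sum(c.n_types * c.points_per_type for c in self.classes)

    def required_dimension(self) -> int:
        # Class directions use the first n_classes basis vectors; type
        # directions reuse the next max(n_types) vectors in every class.
        return self.n_classes + max((c.n_types for c in self.classes), default=0)


@dataclass
class LabeledMatrix:
    """Data matrix with the two-level labels that generated it."""

    data: np.ndarray  # (n, p)
    type_labels: np.ndarray  # (n,) ints in [0, n_types)
    class_labels: np.ndarray  # (n,) ints in [0, n_classes)

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        if not (len(self.type_labels) == len(self.class_labels) == n):
            raise ValueError("labels must have one entry per row of data")


def default_benchmark_spec(seed: int = 42) -> MixtureSpec:
    """The benchmark mixture: 3 classes x 5 types, n = 15,500, 50 dimensions.

    One class has 2000 points per type with within-class shift 4 (its types
    partially overlap); the other two have 1000 and 100 points per type with
    within-class shift 10 (well-separated types).  Class shifts are 20.
    """
    return MixtureSpec(
        dimension=50,
        classes=(
            ClassSpec(between_shift=20.0, within_shift=4.0, n_types=5, points_per_type=2000),
            ClassSpec(between_shift=20.0, within_shift=10.0, n_types=5, points_per_type=1000),
            ClassSpec(between_shift=20.0, within_shift=10.0, n_types=5, points_per_type=100),
        ),
        seed=seed,
    )


def generate(spec: MixtureSpec) -> LabeledMatrix:
    """Sample a :class:`LabeledMatrix` from ``spec``.

    Every row is a standard-normal draw plus its class-mean shift plus its
    type-mean shift.  Shift directions are distinct standard basis vectors in a
    fixed order: class ``c`` is shifted along ``e_c``; type ``t`` of any class
    along ``e_{n_classes + t}``.  Any other orthonormal choice differs from
    this one only by a rotation of the ambient space.

    Raises
    ------
    ValueError
        If ``spec.dimension`` is too small to host the orthogonal shift
        directions (fewer than n_classes + max types per class).
    """
    need = spec.required_dimension()
    if spec.dimension < need:
        raise ValueError(
            f"dimension {spec.dimension} cannot host {spec.n_classes} orthogonal "
            f"class directions plus {need - spec.n_classes} type directions; "
            f"need at least {need}"
        )
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_points, spec.dimension
    data = rng.standard_normal((n, p))
    type_labels = np.empty(n, dtype=np.int64)
    class_labels = np.empty(n, dtype=np.int64)

    row = 0
    global_type = 0
    for ci, cls in enumerate(spec.classes):
        for ti in range(cls.n_types):
            m = cls.points_per_type
            block = slice(row, row + m)
            data[block, ci] += cls.between_shift
            data[block, spec.n_classes + ti] += cls.within_shift
            type_labels[block] = global_type
            class_labels[block] = ci
            row += m
            global_type += 1

    if spec.shuffle:
        perm = rng.permutation(n)
        data, type_labels, class_labels = data[perm], type_labels[perm], class_labels[perm]
    return LabeledMatrix(data=data, type_labels=type_labels, class_labels=class_labels)
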