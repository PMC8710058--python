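"""Cross-dataset DEG set algebra: deriving miR172-dependent "target DEGs".

Dataset A is the transgenic contrast set (miR172OX vs WT at 4 WPFB),
dataset B the cultivar fruit-size contrast (small 'M9' vs large 'Hanfu').
Shared DEGs moving in the same direction in both datasets are generic
fruit-size responders and are excluded; the target set is the union of
the A-specific DEGs and the shared opposite-direction DEGs, so
|target| = |A| - |same_direction| always. The operation is asymmetric in
A and B by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SharedClassification", "TargetDEGSet", "classify_shared", "derive_target_degs"]


@dataclass
class SharedClassification:
    shared: set[str]
    same_direction: set[str]
    opposite_direction: set[str]
    a_specific: set[str]
    b_specific: set[str]

    def __post_init__(self) -> None:
        if self.same_direction | self.opposite_direction != self.shared:
            raise ValueError("same/opposite subsets must partition the shared set")
        if self.same_direction & self.opposite_direction:
            raise ValueError("same/opposite subsets must be disjoint")


@dataclass
class TargetDEGSet:
    """miR172-dependent DEGs with per-gene provenance."""

    genes: set[str]
    provenance: dict[str, str]  # gene -> "A_specific" | "shared_opposite"

    def count_by_provenance(self) -> dict[str, int]:
        out = {"A_specific": 0, "shared_opposite": 0}
        for v in self.provenance.values():
            out[v] += 1
        return out


def classify_shared(
    a: set[str],
    b: set[str],
    dir_a: dict[str, str],
    dir_b: dict[str, str],
) -> SharedClassification:
    """Partition A and B into specific and shared same/opposite-direction sets."""
    a, b = set(a), set(b)
    shared = a & b
    for g in shared:
        if g not in dir_a:
            raise ValueError(f"shared gene {g!r} lacks a direction in dataset A")
        if g not in dir_b:
            raise ValueError(f"shared gene {g!r} lacks a direction in dataset B")
    same = {g for g in shared if dir_a[g] == dir_b[g]}
    return SharedClassification(
        shared=shared,
        same_direction=same,
        opposite_direction=shared - same,
        a_specific=a - shared,
        b_specific=b - shared,
    )


def derive_target_degs(cls: SharedClassification) -> TargetDEGSet:
    """target = A_specific ∪ shared_opposite; |target| = |A| - |same_direction|."""
    prov: dict[str, str] = {}
    for g in cls.a_specific:
        prov[g] = "A_specific"
    for g in cls.opposite_direction:
        prov[g] = "shared_opposite"
    return TargetDEGSet(genes=cls.a_specific | cls.opposite_direction, provenance=prov)
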