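"""Gridding-free design of cascaded dilated convolutions (GHDC).

A cascade of dilated convolutions enlarges the receptive field cheaply, but a
careless choice of dilation rates leaves periodic holes in the set of input
pixels that reach an output unit — the *gridding effect*.  The generalized
hybrid dilated convolution (GHDC) strategy works on the 1-D projection of the
sampling pattern (the 2-D pattern is the outer product of two identical 1-D
patterns, so the 1-D analysis is exact): walking from the top layer ``L`` down
to layer 1, it tracks ``M_l``, the largest distance between neighbouring input
positions of layer ``l`` that are actually sampled, via the offset enumeration

    offsets = { m * r_l + n * M_{l+1} },   |m| <= (k_l-1)/2,  |n| <= (k_{l+1}-1)/2

A cascade is gridding-free when the first layer's dense kernel can bridge the
residual gaps, i.e. ``M_2 <= k_1``.  The receptive field of the cascade is
``F = 1 + sum_l r_l * (k_l - 1)``.

All kernels are odd so that every layer has a unique central pixel and
symmetric padding; dilation is isotropic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "DilatedLayerSpec",
    "CascadeSpec",
    "OffsetSet",
    "GapProfile",
    "CoverageReport",
    "receptive_field",
    "layer_offsets",
    "gap_profile",
    "validate_cascade",
    "coverage_oracle",
    "hdc_reference_gap",
    "design_cascade",
]


@dataclass(frozen=True)
class DilatedLayerSpec:
    """One dilated convolution layer: odd ``kernel_size`` k and ``dilation_rate`` r."""

    kernel_size: int
    dilation_rate: int

    def __post_init__(self) -> None:
        k, r = self.kernel_size, self.dilation_rate
        if not (isinstance(k, int) and k >= 1 and k % 2 == 1):
            raise ValueError(f"kernel_size must be an odd positive integer, got {k!r}")
        if not (isinstance(r, int) and r >= 1):
            raise ValueError(f"dilation_rate must be a positive integer, got {r!r}")

    @property
    def extent(self) -> int:
        """Spatial extent r*(k-1)+1 of the dilated kernel, in pixels."""
        return self.dilation_rate * (self.kernel_size - 1) + 1


@dataclass(frozen=True)
class CascadeSpec:
    """Ordered dilated layers; index 0 is the layer applied first (nearest the input)."""

    layers: tuple[DilatedLayerSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) < 1:
            raise ValueError("a cascade needs at least one layer")

    @classmethod
    def from_lists(cls, rates: Sequence[int], kernels: Sequence[int]) -> "CascadeSpec":
        if len(rates) != len(kernels):
            raise ValueError(
                f"got {len(rates)} dilation rates but {len(kernels)} kernel sizes"
            )
        return cls(tuple(DilatedLayerSpec(k, r) for k, r in zip(kernels, rates)))

    @property
    def rates(self) -> tuple[int, ...]:
        return tuple(l.dilation_rate for l in self.layers)

    @property
    def kernels(self) -> tuple[int, ...]:
        return tuple(l.kernel_size for l in self.layers)

    def __len__(self) -> int:
        return len(self.layers)


@dataclass(frozen=True)
class OffsetSet:
    """Sorted distinct 1-D sample offsets of a layer and their consecutive gaps.

    ``gaps`` is the non-decreasing sequence of differences between neighbouring
    distinct offsets; its maximum is the layer's maximum sampling gap.
    """

    offsets: tuple[int, ...]
    gaps: tuple[int, ...]

    @property
    def max_gap(self) -> int:
        """Largest distance between neighbouring sampled positions (1 if single offset)."""
        return self.gaps[-1] if self.gaps else 1


@dataclass(frozen=True)
class GapProfile:
    """Per-layer maximum sampling gaps of a cascade plus the gridding verdict.

    ``max_gaps[l-1]`` is ``M_l`` for ``l = 1..L+1``; the boundary entry
    ``M_{L+1} = 1`` encodes that the top layer's output is read densely.
    ``valid`` is the gridding-free verdict ``M_2 <= k_1`` (for a single layer,
    ``r_1 == 1``).
    """

    cascade: CascadeSpec
    max_gaps: tuple[int, ...]
    receptive_field: int
    valid: bool
    diagnostic: str = ""

    def M(self, l: int) -> int:
        """Maximum sampling gap M_l, 1-indexed; l may be 1..L+1."""
        if not 1 <= l <= len(self.cascade) + 1:
            raise IndexError(f"layer index {l} outside 1..{len(self.cascade) + 1}")
        return self.max_gaps[l - 1]


@dataclass(frozen=True)
class CoverageReport:
    """Brute-force sampled-offset set of a cascade and its uncovered holes."""

    covered: frozenset[int]
    holes: tuple[int, ...]
    receptive_field: int

    @property
    def has_holes(self) -> bool:
        return len(self.holes) > 0


def receptive_field(cascade: CascadeSpec) -> int:
    """Receptive field F = 1 + sum_l r_l * (k_l - 1) of the cascade, in pixels."""
    return 1 + sum(l.dilation_rate * (l.kernel_size - 1) for l in cascade.layers)


def _check_odd(name: str, k: int) -> None:
    if not (isinstance(k, int) and k >= 1 and k % 2 == 1):
        raise ValueError(f"{name} must be an odd positive integer, got {k!r}")


def layer_offsets(k_l: int, r_l: int, k_up: int, M_up: int) -> OffsetSet:
    """Enumerate the 1-D input offsets sampled through layer ``l``.

    The layer above reads ``k_up`` positions spaced ``M_up`` apart; layer ``l``
    places a ``k_l``-tap kernel with spacing ``r_l`` at each of them, so the
    sampled offsets are ``m * r_l + n * M_up`` with ``|m| <= (k_l-1)/2`` and
    ``|n| <= (k_up-1)/2``.  Duplicates collapse before differencing.
    """
    _check_odd("k_l", k_l)
    _check_odd("k_up", k_up)
    if not (isinstance(r_l, int) and r_l >= 1):
        raise ValueError(f"r_l must be a positive integer, got {r_l!r}")
    if not (isinstance(M_up, int) and M_up >= 1):
        raise ValueError(f"M_up must be a positive integer, got {M_up!r}")
    half_m = (k_l - 1) // 2
    half_n = (k_up - 1) // 2
    offsets = sorted(
        {
            m * r_l + n * M_up
            for m in range(-half_m, half_m + 1)
            for n in range(-half_n, half_n + 1)
        }
    )
    gaps = tuple(sorted(b - a for a, b in zip(offsets, offsets[1:])))
    return OffsetSet(offsets=tuple(offsets), gaps=gaps)


def gap_profile(cascade: CascadeSpec) -> GapProfile:
    """Run the top-down gap recursion and report M_1..M_{L+1} plus the verdict.

    The recursion starts from the boundary convention ``k_{L+1} = 1``,
    ``M_{L+1} = 1`` (the cascade output is consumed densely), which makes
    ``M_L = r_L``.  A cascade is gridding-free when ``M_2 <= k_1``; a lone
    dilated layer is gridding-free only for ``r_1 = 1``.
    """
    L = len(cascade)
    max_gaps = [0] * (L + 1)
    max_gaps[L] = 1  # M_{L+1}
    k_up, M_up = 1, 1
    for l in range(L, 0, -1):
        layer = cascade.layers[l - 1]
        off = layer_offsets(layer.kernel_size, layer.dilation_rate, k_up, M_up)
        max_gaps[l - 1] = off.max_gap
        k_up, M_up = layer.kernel_size, off.max_gap
    if L == 1:
        valid = cascade.layers[0].dilation_rate == 1
    else:
        valid = max_gaps[1] <= cascade.layers[0].kernel_size
    return GapProfile(
        cascade=cascade,
        max_gaps=tuple(max_gaps),
        receptive_field=receptive_field(cascade),
        valid=valid,
    )


def validate_cascade(cascade: CascadeSpec) -> GapProfile:
    """gap_profile plus a human-readable diagnostic naming where coverage breaks."""
    profile = gap_profile(cascade)
    L = len(cascade)
    lines = [
        f"cascade rates={list(cascade.rates)} kernels={list(cascade.kernels)}: "
        f"F={profile.receptive_field}",
        "per-layer maximum sampling gaps: "
        + ", ".join(f"M{l}={profile.M(l)}" for l in range(1, L + 2)),
    ]
    if profile.valid:
        lines.append("gridding-free: every input pixel inside the receptive field is sampled")
    elif L == 1:
        lines.append(
            f"coverage breaks at layer 1: a single dilated layer with rate "
            f"{cascade.layers[0].dilation_rate} > 1 skips pixels between its taps"
        )
    else:
        lines.append(
            f"coverage breaks at layer 1: the feature map entering layer 2 has "
            f"sampling gaps of {profile.M(2)} px, wider than the layer-1 kernel "
            f"size {cascade.layers[0].kernel_size} can bridge (M2 <= k1 violated)"
        )
    return GapProfile(
        cascade=profile.cascade,
        max_gaps=profile.max_gaps,
        receptive_field=profile.receptive_field,
        valid=profile.valid,
        diagnostic="\n".join(lines),
    )


def coverage_oracle(cascade: CascadeSpec, max_receptive_field: int = 1001) -> CoverageReport:
    """Brute-force check: enumerate every input offset reachable through the cascade.

    Builds the Minkowski sum ``{ sum_l m_l * r_l }`` over all kernel-tap
    choices, i.e. the exact set of input pixels (1-D projection) that influence
    one output unit, and lists the holes inside ``[-(F-1)/2, (F-1)/2]``.
    Independent of the gap recursion; exponential in cascade size, hence the
    receptive-field bound.
    """
    F = receptive_field(cascade)
    if F > max_receptive_field:
        raise ValueError(
            f"receptive field {F} exceeds enumeration bound {max_receptive_field}"
        )
    covered = {0}
    for layer in cascade.layers:
        half = (layer.kernel_size - 1) // 2
        taps = [m * layer.dilation_rate for m in range(-half, half + 1)]
        covered = {c + t for c in covered for t in taps}
    half_f = (F - 1) // 2
    holes = tuple(x for x in range(-half_f, half_f + 1) if x not in covered)
    return CoverageReport(covered=frozenset(covered), holes=holes, receptive_field=F)


def hdc_reference_gap(r_l: int, M_up: int) -> int:
    """Closed-form gap update for the kernel-size-3 (HDC) regime.

    Printed branches: ``M_l = r_l`` when ``0 < M_up < r_l`` and
    ``M_l = max(r_l, M_up - 2*r_l)`` when ``M_up > 2*r_l``.  The intermediate
    case ``r_l <= M_up <= 2*r_l`` has no printed closed form and falls back to
    the exact offset enumeration with k=3 above and below.  The first branch is
    a conservative upper bound on the exact gap (it equals it at the top of a
    cascade, where the layer above collapses to a single read position).
    """
    if not (isinstance(r_l, int) and r_l >= 1):
        raise ValueError(f"r_l must be a positive integer, got {r_l!r}")
    if not (isinstance(M_up, int) and M_up >= 1):
        raise ValueError(f"M_up must be a positive integer, got {M_up!r}")
    if M_up < r_l:
        return r_l
    if M_up > 2 * r_l:
        return max(r_l, M_up - 2 * r_l)
    return layer_offsets(3, r_l, 3, M_up).max_gap


def design_cascade(
    num_layers: int,
    kernel_options: Iterable[int],
    max_rate: int,
    min_receptive_field: int,
) -> list[CascadeSpec]:
    """Enumerate gridding-free cascades and rank them.

    Searches non-decreasing dilation-rate sequences up to ``max_rate`` with
    kernels drawn from ``kernel_options``, keeps designs that pass
    :func:`validate_cascade` with receptive field at least
    ``min_receptive_field``, and returns them sorted by descending receptive
    field, then ascending ``sum(k^2)`` (a parameter-cost proxy), then the
    rate/kernel tuples for a fully deterministic order.
    """
    kernels = sorted(set(kernel_options))
    if not kernels:
        raise ValueError("kernel_options must be non-empty")
    for k in kernels:
        _check_odd("kernel option", k)
    if num_layers < 1:
        raise ValueError("num_layers must be >= 1")
    results: list[CascadeSpec] = []
    rate_seqs = itertools.combinations_with_replacement(range(1, max_rate + 1), num_layers)
    for rates in rate_seqs:  # combinations_with_replacement yields non-decreasing seqs
        for ks in itertools.product(kernels, repeat=num_layers):
            cascade = CascadeSpec.from_lists(rates, ks)
            profile = gap_profile(cascade)
            if profile.valid and profile.receptive_field >= min_receptive_field:
                results.append(cascade)
    results.sort(
        key=lambda c: (
            -receptive_field(c),
            sum(k * k for k in c.kernels),
            c.rates,
            c.kernels,
        )
    )
    return results
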